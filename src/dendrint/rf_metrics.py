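"""Receptive-field geometry metrics linking RFs to dendritic structure.

For each ROI that passes the quality filter we relate the position of its RF
contour to the recording site and the dendritic arbour: the offset distance
(ROI centre to RF-contour centroid), the offset angle (0° when the RF is
shifted exactly toward the arbour's centre of mass), the pairwise RF overlap
index Oi = A_overlap / min(A1, A2), and hexagonally binned overlap maps as a
function of dendritic and angular distance between ROI pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import InvalidArgumentError, UndefinedMetricError

HEX_DX_DEFAULT = 25.0    # µm bin pitch along dendritic distance
HEX_DY_DEFAULT = 15.0    # degrees bin pitch along angular distance
HEX_MIN_COUNT = 3        # bins with fewer pairs are masked


def offset_distance(roi_centre, rf_centre) -> float:
    """Euclidean distance (µm) between ROI centre and RF-contour centroid."""
    a = np.asarray(roi_centre, float)
    b = np.asarray(rf_centre, float)
    return float(np.linalg.norm(a - b))


def offset_angle(roi_centre, rf_centre, arbour_centre) -> float:
    """Angle in [0°, 180°] between the ROI→RF-centre and ROI→arbour-centre
    directions; 0° means the RF is shifted exactly toward the arbour centre."""
    roi = np.asarray(roi_centre, float)
    u = np.asarray(rf_centre, float) - roi
    v = np.asarray(arbour_centre, float) - roi
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UndefinedMetricError("zero-length offset vector")
    cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _as_polygon(contour) -> Polygon:
    arr = getattr(contour, "polygon", contour)
    shp = Polygon(np.asarray(arr, float))
    if not shp.is_valid:
        shp = shp.buffer(0)
    return shp


def overlap_index(contour_a, contour_b) -> float:
    """RF overlap index Oi = A_overlap / min(A1, A2), in [0, 1].

    Symmetric; 1 for identical or nested contours, 0 for disjoint ones.
    Polygon intersection uses exact polygon clipping."""
    pa, pb = _as_polygon(contour_a), _as_polygon(contour_b)
    if pa.area <= 0 or pb.area <= 0:
        raise InvalidArgumentError("zero-area polygon")
    inter = pa.intersection(pb).area
    return float(inter / min(pa.area, pb.area))


@dataclass
class OverlapMap:
    """Hex-binned mean overlap index over (dendritic distance, angle) pairs."""

    centres: np.ndarray      # (n_bins, 2): bin centres (µm, degrees)
    means: np.ndarray        # per-bin mean Oi (NaN where masked)
    counts: np.ndarray       # per-bin pair counts
    dx: float
    dy: float
    min_count: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "distance_um": self.centres[:, 0],
            "angle_deg": self.centres[:, 1],
            "mean_oi": self.means,
            "count": self.counts,
        })


def _hex_assign(x, y, dx, dy):
    """Assign points to a hexagonal lattice built from two interleaved
    rectangular lattices (pitch dx × dy; the second offset by half a pitch),
    the same construction matplotlib's hexbin uses. Returns per-point integer
    bin ids ``(lattice, ix, iy)`` and the corresponding bin centres."""
    u = np.asarray(x, float) / dx
    v = np.asarray(y, float) / dy
    ix1, iy1 = np.round(u), np.round(v)
    ix2, iy2 = np.floor(u) + 0.5, np.floor(v) + 0.5
    d1 = (u - ix1) ** 2 + 3.0 * (v - iy1) ** 2
    d2 = (u - ix2) ** 2 + 3.0 * (v - iy2) ** 2
    use2 = d2 < d1
    cx = np.where(use2, ix2, ix1)
    cy = np.where(use2, iy2, iy1)
    ids = np.stack([use2.astype(int),
                    np.round(2 * cx).astype(int),
                    np.round(2 * cy).astype(int)], axis=1)
    centres = np.column_stack([cx * dx, cy * dy])
    return ids, centres


def overlap_map(pairs, dx: float = HEX_DX_DEFAULT, dy: float = HEX_DY_DEFAULT,
                min_count: int = HEX_MIN_COUNT) -> OverlapMap:
    """Hex-bin (Oi, dendritic distance, angular distance) triples.

    ``pairs`` is an iterable of (oi, distance_µm, angle_deg) or a DataFrame
    with those columns. Per-bin means are reported; bins with fewer than
    ``min_count`` pairs have their mean masked (NaN) but keep their count.
    The total of bin counts always equals the number of input pairs.
    """
    if isinstance(pairs, pd.DataFrame):
        arr = pairs[["oi", "distance_um", "angle_deg"]].to_numpy(float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        return OverlapMap(np.empty((0, 2)), np.empty(0), np.empty(0, int),
                          dx, dy, min_count)
    oi, dist, ang = arr[:, 0], arr[:, 1], arr[:, 2]
    ids, centres_pt = _hex_assign(dist, ang, dx, dy)
    uniq, first, inv = np.unique(ids, axis=0, return_index=True,
                                 return_inverse=True)
    counts = np.bincount(inv)
    sums = np.bincount(inv, weights=oi)
    means = sums / counts
    means = np.where(counts >= min_count, means, np.nan)
    centres = centres_pt[first]
    return OverlapMap(centres, means, counts, dx, dy, min_count)


def rf_area_vs_distance(cells) -> pd.DataFrame:
    """Tidy pooled table of RF area vs dendritic distance to soma.

    ``cells`` is an iterable of dicts (or objects) with keys ``cell_id``,
    ``cell_type`` and ``rois``; each ROI entry carries ``roi_id``,
    ``distance_um`` (dendritic path distance to the soma) and ``rf_area_um2``
    for ROIs that passed the RF quality filter. Returns one row per ROI,
    pooled across cells, ready for downstream smoothing/plotting.
    """
    rows = []
    for cell in cells:
        get = cell.get if isinstance(cell, dict) else lambda k: getattr(cell, k)
        for roi in get("rois"):
            rget = roi.get if isinstance(roi, dict) else lambda k: getattr(roi, k)
            rows.append({
                "cell_id": get("cell_id"),
                "type": get("cell_type"),
                "roi_id": rget("roi_id"),
                "distance_um": float(rget("distance_um")),
                "rf_area_um2": float(rget("rf_area_um2")),
            })
    return pd.DataFrame(rows, columns=["cell_id", "type", "roi_id",
                                       "distance_um", "rf_area_um2"])
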