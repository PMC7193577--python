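"""Skeleton data model and morphological analysis of single-cell dendritic arbours.

A reconstructed cell is a rooted tree of 3D nodes with radii (SWC-style).
From it we compute the four parameters used to separate Off retinal ganglion
cell (RGC) types -- marginal-central arbour density difference, convex-hull
arbour area, arbour asymmetry, and soma size -- plus the inter-ROI path
metrics (dendritic and angular distance) that spatial-integration analyses
are conditioned on, and the fixed three-step hierarchical clustering that
assigns each cell to one of {tOff alpha, tOff mini, sOff, F-miniOff}.

Depth within the inner plexiform layer (IPL) is expressed on a normalized
axis where the blood-vessel plexus at the ganglion-cell layer is 0 and the
one at the inner nuclear layer is 1; the On and Off ChAT bands sit at 0.48
and 0.77 on this axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import ConvexHull
from sklearn.cluster import KMeans

from .errors import InvalidArgumentError, UndefinedMetricError

#: default a.u. scale applied to the normalized arbour density difference so
#: that generator targets on the reference-type scale can be matched.
ADD_SCALE_DEFAULT = 10.0

RGC_TYPES = ("tOff alpha", "tOff mini", "sOff", "F-miniOff")


@dataclass(frozen=True)
class ChATFrame:
    """Relative IPL depths of the On and Off ChAT bands."""

    on_chat_depth: float = 0.48
    off_chat_depth: float = 0.77

    def __post_init__(self):
        if not (0.0 < self.on_chat_depth < self.off_chat_depth < 1.0):
            raise InvalidArgumentError(
                "require 0 < on_chat_depth < off_chat_depth < 1"
            )


@dataclass(frozen=True)
class MorphoParams:
    """The four morphological parameters of one cell."""

    arbour_density_difference: float  # a.u.
    area: float  # µm²
    asymmetry: float  # µm (a.u.)
    soma_size: float  # µm²

    def __post_init__(self):
        if self.area <= 0 or self.soma_size <= 0:
            raise InvalidArgumentError("area and soma_size must be positive")


class Skeleton:
    """Rooted tree of 3D nodes with radii.

    Parameters
    ----------
    ids, parents
        Integer node ids and parent ids (parent ``-1`` marks the single root,
        the soma). Parent links must form a tree.
    xyz
        ``(n, 3)`` node positions in µm.
    radius
        Per-node radii in µm (``> 0``).
    ipl_axis
        ``(z_gcl, z_inl)`` -- the z coordinates mapped to relative IPL depth
        0 and 1. Defaults to ``None`` (depth-dependent metrics unavailable).
    """

    def __init__(self, ids, parents, xyz, radius, ipl_axis=None):
        self.ids = np.asarray(ids, dtype=int)
        self.parents = np.asarray(parents, dtype=int)
        self.xyz = np.asarray(xyz, dtype=float)
        self.radius = np.asarray(radius, dtype=float)
        self.ipl_axis = None if ipl_axis is None else (float(ipl_axis[0]), float(ipl_axis[1]))
        self._validate()
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        self._graph = None

    def _validate(self):
        n = len(self.ids)
        if self.xyz.shape != (n, 3) or len(self.parents) != n or len(self.radius) != n:
            raise InvalidArgumentError("inconsistent skeleton array lengths")
        if len(np.unique(self.ids)) != n:
            raise InvalidArgumentError("duplicate node ids")
        roots = np.flatnonzero(self.parents == -1)
        if len(roots) != 1:
            raise InvalidArgumentError(f"expected exactly one root, found {len(roots)}")
        if np.any(self.radius <= 0):
            raise InvalidArgumentError("radii must be positive")
        idset = set(self.ids.tolist())
        for i, p in zip(self.ids, self.parents):
            if p != -1 and p not in idset:
                raise InvalidArgumentError(f"node {i} references missing parent {p}")
        # acyclicity: walk each node to the root, counting steps
        parent_of = dict(zip(self.ids.tolist(), self.parents.tolist()))
        for i in self.ids.tolist():
            seen = 0
            j = i
            while j != -1:
                j = parent_of[j]
                seen += 1
                if seen > len(self.ids):
                    raise InvalidArgumentError("parent links contain a cycle")

    # -- basic structure -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root_index(self) -> int:
        return int(np.flatnonzero(self.parents == -1)[0])

    @property
    def soma_id(self) -> int:
        return int(self.ids[self.root_index])

    @property
    def soma_xyz(self) -> np.ndarray:
        return self.xyz[self.root_index]

    @property
    def soma_radius(self) -> float:
        return float(self.radius[self.root_index])

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def edges(self) -> np.ndarray:
        """``(m, 2)`` array of (child_index, parent_index) rows."""
        child = np.flatnonzero(self.parents != -1)
        parent = np.array([self._index[int(p)] for p in self.parents[child]])
        return np.column_stack([child, parent])

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.xyz[e[:, 0]] - self.xyz[e[:, 1]], axis=1)

    def total_length(self) -> float:
        return float(self.edge_lengths().sum())

    def depth_of_z(self, z) -> np.ndarray:
        if self.ipl_axis is None:
            raise InvalidArgumentError("skeleton has no ipl_axis; cannot map z to IPL depth")
        z0, z1 = self.ipl_axis
        return (np.asarray(z, dtype=float) - z0) / (z1 - z0)

    def graph(self) -> nx.Graph:
        """Undirected tree with edge-length weights, built lazily."""
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(range(self.n_nodes))
            for c, p in self.edges():
                w = float(np.linalg.norm(self.xyz[c] - self.xyz[p]))
                g.add_edge(int(c), int(p), weight=w)
            self._graph = g
        return self._graph

    def children(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {k: [] for k in range(self.n_nodes)}
        for c, p in self.edges():
            out[int(p)].append(int(c))
        return out

    def branch_orders(self) -> np.ndarray:
        """Branch order per node: primary dendrites are order 1 and the
        order increments at every branching node (and at the soma)."""
        kids = self.children()
        order = np.zeros(self.n_nodes, dtype=int)
        root = self.root_index
        stack = [(root, 0)]
        while stack:
            node, o = stack.pop()
            order[node] = o
            bump = node == root or len(kids[node]) >= 2
            for c in kids[node]:
                stack.append((c, o + 1 if bump else o))
        return order


@dataclass(frozen=True)
class RoiAttachment:
    """A ROI centre snapped to the nearest point on a skeleton edge."""

    child_index: int
    parent_index: int
    t: float                 # position along edge: 0 at child node, 1 at parent
    point: np.ndarray        # 3D attachment point, µm
    distance: float          # Euclidean snap distance, µm
    matched: bool = True


# ---------------------------------------------------------------------------
# Morphological parameters
# ---------------------------------------------------------------------------

def _central_fraction_of_edge(d0: float, d1: float, chat: ChATFrame) -> float:
    """Fraction of an edge (linear depth profile d0 -> d1) lying between the
    ChAT bands. Exact for straight edges."""
    lo, hi = chat.on_chat_depth, chat.off_chat_depth
    if d0 == d1:
        return 1.0 if lo <= d0 <= hi else 0.0
    a, b = sorted((d0, d1))
    inter = max(0.0, min(b, hi) - max(a, lo))
    return inter / (b - a)


def arbour_density_difference(
    skeleton: Skeleton,
    chat_frame: ChATFrame = ChATFrame(),
    scale: float = ADD_SCALE_DEFAULT,
) -> float:
    """Normalized central-minus-marginal dendritic length difference.

    Central IPL is the stratum between the ChAT bands; everything else is
    marginal. Returns ``scale * (L_central - L_marginal) / L_total``, bounded
    in ``[-scale, +scale]``. Edges crossing a band boundary are split
    analytically.
    """
    e = skeleton.edges()
    if len(e) == 0:
        raise InvalidArgumentError("skeleton has zero dendritic length")
    lengths = skeleton.edge_lengths()
    total = float(lengths.sum())
    if total <= 0:
        raise InvalidArgumentError("skeleton has zero dendritic length")
    d = skeleton.depth_of_z(skeleton.xyz[:, 2])
    central = 0.0
    for (c, p), L in zip(e, lengths):
        central += L * _central_fraction_of_edge(d[c], d[p], chat_frame)
    marginal = total - central
    return scale * (central - marginal) / total


def _resampled_projection(skeleton: Skeleton, spacing: float = 1.0) -> np.ndarray:
    """Z-projected points sampled every `spacing` µm along every edge
    (both endpoints always included)."""
    pts = [skeleton.xyz[:, :2]]
    for c, p in skeleton.edges():
        a, b = skeleton.xyz[c], skeleton.xyz[p]
        L = float(np.linalg.norm(b - a))
        n = int(L // spacing)
        if n >= 1:
            t = (np.arange(1, n + 1) / (n + 1))[:, None]
            pts.append((a[None, :2] * (1 - t) + b[None, :2] * t))
    return np.vstack(pts)


def arbour_area(skeleton: Skeleton, spacing: float = 1.0) -> float:
    """Area (µm²) of the tightest convex hull of the z-projected arbour.

    Edges are densely resampled (default 1 µm) before hull computation; the
    soma node is included.
    """
    pts = _resampled_projection(skeleton, spacing)
    if len(pts) < 3:
        raise InvalidArgumentError("need at least 3 projected points")
    try:
        hull = ConvexHull(pts)
    except Exception as err:  # qhull raises on degenerate (collinear) input
        raise InvalidArgumentError(f"degenerate (collinear) arbour: {err}") from err
    return float(hull.volume)  # in 2D, .volume is the area


def asymmetry(skeleton: Skeleton) -> float:
    """Distance (µm, z-projection) between the length-weighted centre of mass
    of the dendritic cable and the soma."""
    e = skeleton.edges()
    lengths = skeleton.edge_lengths()
    total = float(lengths.sum())
    if total <= 0:
        raise InvalidArgumentError("skeleton has zero dendritic length")
    mid = 0.5 * (skeleton.xyz[e[:, 0], :2] + skeleton.xyz[e[:, 1], :2])
    centroid = (mid * lengths[:, None]).sum(axis=0) / total
    return float(np.linalg.norm(centroid - skeleton.soma_xyz[:2]))


def soma_size(skeleton: Skeleton = None, soma_mask: np.ndarray = None,
              pixel_area: float = 1.0) -> float:
    """Soma area (µm²): from the SWC soma sphere (``π r²``) or from a
    segmented mask of the frame where the soma appears largest."""
    if soma_mask is not None:
        mask = np.asarray(soma_mask, dtype=bool)
        if mask.sum() == 0:
            raise InvalidArgumentError("empty soma mask")
        return float(mask.sum() * pixel_area)
    if skeleton is None:
        raise InvalidArgumentError("provide a skeleton or a soma mask")
    return float(np.pi * skeleton.soma_radius ** 2)


def morpho_params(skeleton: Skeleton, chat_frame: ChATFrame = ChATFrame(),
                  add_scale: float = ADD_SCALE_DEFAULT) -> MorphoParams:
    """All four clustering parameters of one cell."""
    return MorphoParams(
        arbour_density_difference=arbour_density_difference(skeleton, chat_frame, add_scale),
        area=arbour_area(skeleton),
        asymmetry=asymmetry(skeleton),
        soma_size=soma_size(skeleton),
    )


def branch_order_profile(skeleton: Skeleton):
    """Median radius and median segment length per branch order.

    A segment is the unbranched cable between two consecutive branching
    nodes (or a branching node and a tip). Returns a dict
    ``order -> (median_radius_µm, median_segment_length_µm)``.
    """
    kids = skeleton.children()
    orders = skeleton.branch_orders()
    radii: dict[int, list[float]] = {}
    seglen: dict[int, list[float]] = {}
    root = skeleton.root_index
    # walk each segment start (root children and children of branch points)
    starts = []
    for node in range(skeleton.n_nodes):
        if node == root or len(kids[node]) >= 2:
            starts.extend(kids[node])
    for start in starts:
        o = int(orders[start])
        length = 0.0
        rads = []
        node = start
        p = skeleton.index_of(int(skeleton.parents[start]))
        while True:
            length += float(np.linalg.norm(skeleton.xyz[node] - skeleton.xyz[p]))
            rads.append(float(skeleton.radius[node]))
            if len(kids[node]) != 1:
                break
            p, node = node, kids[node][0]
        radii.setdefault(o, []).extend(rads)
        seglen.setdefault(o, []).append(length)
    return {
        o: (float(np.median(radii[o])), float(np.median(seglen[o])))
        for o in sorted(seglen)
    }


# ---------------------------------------------------------------------------
# ROI calibration and path metrics
# ---------------------------------------------------------------------------

def calibrate_rois(skeleton: Skeleton, roi_centres, max_distance: float = 10.0
                   ) -> list[RoiAttachment]:
    """Snap ROI centres to the nearest point on the nearest skeleton edge.

    ROIs farther than ``max_distance`` µm from every edge are returned with
    ``matched=False``. Centres may be 2D (z-projection; matched against
    projected edges) or 3D.
    """
    centres = np.asarray(roi_centres, dtype=float)
    if centres.ndim == 1:
        centres = centres[None, :]
    dims = centres.shape[1]
    if dims not in (2, 3):
        raise InvalidArgumentError("roi centres must be 2D or 3D")
    e = skeleton.edges()
    if len(e) == 0:
        raise InvalidArgumentError("skeleton has no edges")
    a = skeleton.xyz[e[:, 0], :dims]   # child endpoints
    b = skeleton.xyz[e[:, 1], :dims]   # parent endpoints
    ab = b - a
    denom = (ab ** 2).sum(axis=1)
    denom[denom == 0] = 1.0
    out = []
    for c in centres:
        t = ((c[None, :] - a) * ab).sum(axis=1) / denom
        t = np.clip(t, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(proj - c[None, :], axis=1)
        k = int(np.argmin(d))
        point = skeleton.xyz[e[k, 0]] * (1 - t[k]) + skeleton.xyz[e[k, 1]] * t[k]
        out.append(RoiAttachment(
            child_index=int(e[k, 0]), parent_index=int(e[k, 1]),
            t=float(t[k]), point=point, distance=float(d[k]),
            matched=bool(d[k] <= max_distance),
        ))
    return out


def _attachment_offsets(skeleton: Skeleton, att: RoiAttachment) -> dict[int, float]:
    """Path length from the attachment point to each of its edge endpoints."""
    L = float(np.linalg.norm(skeleton.xyz[att.child_index] - skeleton.xyz[att.parent_index]))
    return {att.child_index: att.t * L, att.parent_index: (1 - att.t) * L}


def dendritic_distance(skeleton: Skeleton, roi_a: RoiAttachment,
                       roi_b: RoiAttachment) -> float:
    """Shortest path length along the dendrite between two attached ROIs (µm)."""
    for att in (roi_a, roi_b):
        if not att.matched:
            raise InvalidArgumentError("ROI is not attached to the skeleton")
    if {roi_a.child_index, roi_a.parent_index} == {roi_b.child_index, roi_b.parent_index}:
        # same edge: walk along it
        L = float(np.linalg.norm(
            skeleton.xyz[roi_a.child_index] - skeleton.xyz[roi_a.parent_index]))
        return abs(roi_a.t - roi_b.t) * L
    g = skeleton.graph()
    offs_a = _attachment_offsets(skeleton, roi_a)
    offs_b = _attachment_offsets(skeleton, roi_b)
    best = np.inf
    for ua, da in offs_a.items():
        sp = nx.single_source_dijkstra_path_length(g, ua)
        for ub, db in offs_b.items():
            best = min(best, da + sp[ub] + db)
    return float(best)


def _path_to_root(skeleton: Skeleton, node: int) -> list[int]:
    parent_of = {skeleton.index_of(i): (
        -1 if p == -1 else skeleton.index_of(p))
        for i, p in zip(skeleton.ids.tolist(), skeleton.parents.tolist())}
    path = [node]
    while parent_of[path[-1]] != -1:
        path.append(parent_of[path[-1]])
    return path


def angular_distance(skeleton: Skeleton, roi_a: RoiAttachment,
                     roi_b: RoiAttachment) -> float:
    """Positive planar angle (degrees, in the z-projection) subtended by two
    ROI positions at the last common branching node of their connecting path.

    The soma counts as a branching node, so ROIs on different primary
    dendrites are measured at the soma.
    """
    pa = _path_to_root(skeleton, roi_a.child_index)
    pb = _path_to_root(skeleton, roi_b.child_index)
    in_b = set(pb)
    lca = next(n for n in pa if n in in_b)
    # walk from the LCA toward the root until a branching node or the soma
    kids = skeleton.children()
    root = skeleton.root_index
    parent_of = {c: p for c, p in skeleton.edges()}
    vertex = lca
    while vertex != root and len(kids[vertex]) < 2:
        vertex = int(parent_of[vertex])
    v = skeleton.xyz[vertex, :2]
    ua = roi_a.point[:2] - v
    ub = roi_b.point[:2] - v
    na, nb = np.linalg.norm(ua), np.linalg.norm(ub)
    if na == 0 or nb == 0:
        raise UndefinedMetricError("ROI coincides with the branching vertex")
    cosang = np.clip(np.dot(ua, ub) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# Hierarchical clustering (three fixed 1D 2-means splits)
# ---------------------------------------------------------------------------

def _split_1d(values: np.ndarray) -> np.ndarray:
    """Deterministic 1D k-means with k=2, initialized at the extremes.

    Returns a boolean array that is True for members of the *upper* cluster.
    Ties (all-identical values) go to the lower cluster with a warning.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise InvalidArgumentError("need at least 2 cells per split")
    if np.allclose(v, v[0]):
        warnings.warn("all values identical at a clustering split; "
                      "assigning every cell to the lower cluster")
        return np.zeros(len(v), dtype=bool)
    init = np.array([[v.min()], [v.max()]])
    km = KMeans(n_clusters=2, init=init, n_init=1).fit(v[:, None])
    labels = km.labels_
    upper = labels == int(np.argmax(km.cluster_centers_.ravel()))
    return upper


def cluster_morphologies(params_table) -> np.ndarray:
    """Assign each cell to one of the four Off RGC types.

    The splits follow a fixed decision tree of 1D 2-means clusterings:

    1. arbour density difference: low vs high;
    2. low-ADD cells split on soma size -> large = tOff alpha, small = tOff mini;
    3. high-ADD cells split on asymmetry -> high = F-miniOff, low = sOff.

    Parameters
    ----------
    params_table
        A pandas DataFrame with columns ``arbour_density_difference``,
        ``area``, ``asymmetry``, ``soma_size`` (or a sequence of
        :class:`MorphoParams`).

    Returns
    -------
    numpy array of type-name strings, aligned with the input rows.
    """
    import pandas as pd

    if not isinstance(params_table, pd.DataFrame):
        params_table = pd.DataFrame([vars(p) for p in params_table])
    required = {"arbour_density_difference", "asymmetry", "soma_size"}
    missing = required - set(params_table.columns)
    if missing:
        raise InvalidArgumentError(f"params table missing columns: {sorted(missing)}")
    n = len(params_table)
    if n < 4:
        raise InvalidArgumentError("need at least 4 cells to resolve 4 types")
    labels = np.empty(n, dtype=object)
    add = params_table["arbour_density_difference"].to_numpy(dtype=float)
    high_add = _split_1d(add)
    low_idx = np.flatnonzero(~high_add)
    high_idx = np.flatnonzero(high_add)
    if len(low_idx) >= 2:
        soma = params_table["soma_size"].to_numpy(dtype=float)[low_idx]
        big = _split_1d(soma)
        labels[low_idx[big]] = "tOff alpha"
        labels[low_idx[~big]] = "tOff mini"
    else:
        labels[low_idx] = "tOff alpha"
    if len(high_idx) >= 2:
        asym = params_table["asymmetry"].to_numpy(dtype=float)[high_idx]
        hi = _split_1d(asym)
        labels[high_idx[hi]] = "F-miniOff"
        labels[high_idx[~hi]] = "sOff"
    else:
        labels[high_idx] = "sOff"
    return labels
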