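"""Correlation-based ROI extraction from time-lapsed Ca²⁺ image stacks.

The procedure mirrors the classical pixel-correlation approach for dendritic
two-photon recordings: (1) compute an s.d. image over time, (2) call pixels
brighter than mean + 1 s.d. of that image "dendritic", (3) derive a
field-specific correlation threshold ρ_threshold as the mean pairwise
correlation among the 100 most responsive dendritic pixels, and (4) grow
ROIs by grouping neighbouring pixels (within 3 µm) whose traces correlate
with the seed trace above ρ_threshold. All steps are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .io import ImageStack

GROUPING_RADIUS_UM = 3.0   # neighbourhood radius for ROI growth
N_TOP_PIXELS = 100         # pixels entering the ρ_threshold estimate


@dataclass
class ROI:
    """A correlated-pixel region and its extracted trace."""

    pixel_mask: np.ndarray        # boolean H×W
    centre: np.ndarray            # (row_µm, col_µm) centroid of the mask
    trace: np.ndarray             # length-T mean trace
    rho_threshold_used: float

    @property
    def n_pixels(self) -> int:
        return int(self.pixel_mask.sum())

    def pixels(self) -> np.ndarray:
        return np.argwhere(self.pixel_mask)


def sd_image(stack: ImageStack) -> np.ndarray:
    """Per-pixel temporal standard deviation (population, ddof=0)."""
    return stack.data.std(axis=0, ddof=0)


def dendritic_pixel_mask(sd_img: np.ndarray) -> np.ndarray:
    """Pixels brighter than mean + 1 s.d. of the s.d. image."""
    sd_img = np.asarray(sd_img, dtype=float)
    if not np.all(np.isfinite(sd_img)):
        raise InvalidArgumentError("sd image contains non-finite values")
    thr = sd_img.mean() + sd_img.std(ddof=0)
    mask = sd_img > thr
    if not mask.any():
        warnings.warn("uniform s.d. image: no dendritic pixels found")
    return mask


def _pixel_traces(stack: ImageStack, rows, cols) -> np.ndarray:
    return stack.data[:, rows, cols].T  # (n_pixels, T)


def correlation_threshold(stack: ImageStack, mask: np.ndarray,
                          n_top: int = N_TOP_PIXELS) -> float:
    """Mean pairwise Pearson correlation among the ``n_top`` most responsive
    (highest-s.d.) dendritic pixels. Fields with fewer dendritic pixels use
    all of them; zero-variance pixel traces are excluded."""
    rows, cols = np.nonzero(mask)
    if len(rows) < 2:
        raise InvalidArgumentError("need at least 2 dendritic pixels")
    sd = stack.data[:, rows, cols].std(axis=0, ddof=0)
    keep = sd > 0
    rows, cols, sd = rows[keep], cols[keep], sd[keep]
    if len(rows) < 2:
        raise InvalidArgumentError("fewer than 2 dendritic pixels with variance")
    order = np.argsort(sd)[::-1][:n_top]
    traces = _pixel_traces(stack, rows[order], cols[order])
    r = np.corrcoef(traces)
    iu = np.triu_indices(len(traces), k=1)
    return float(r[iu].mean())


def grow_rois(stack: ImageStack, mask: np.ndarray, rho_threshold: float,
              pixel_size: float | None = None, min_size: int = 1) -> list[ROI]:
    """Greedy seeded region growth of ROIs.

    Seeds are unassigned dendritic pixels in descending s.d. order. A region
    repeatedly absorbs unassigned dendritic pixels lying within 3 µm of any
    current member whose trace correlates with the *seed* trace above
    ``rho_threshold``, until stable. Resulting masks are disjoint.
    """
    if pixel_size is None:
        pixel_size = stack.pixel_size
    H, W = stack.data.shape[1:]
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        return []
    sd = stack.data[:, rows, cols].std(axis=0, ddof=0)
    order = np.argsort(sd)[::-1]
    coords = np.column_stack([rows, cols]).astype(float)
    assigned = np.zeros(len(rows), dtype=bool)
    radius_px = GROUPING_RADIUS_UM / pixel_size
    traces = _pixel_traces(stack, rows, cols)
    tz = traces - traces.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(tz, axis=1)
    rois: list[ROI] = []
    for seed in order:
        if assigned[seed]:
            continue
        if norms[seed] == 0:
            assigned[seed] = True
            continue
        member = np.zeros(len(rows), dtype=bool)
        member[seed] = True
        # correlation of every pixel with the seed trace
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = tz @ tz[seed] / (norms * norms[seed])
        corr[norms == 0] = -np.inf
        changed = True
        while changed:
            changed = False
            cand = ~assigned & ~member & (corr > rho_threshold)
            if not cand.any():
                break
            d = np.linalg.norm(
                coords[cand][:, None, :] - coords[member][None, :, :], axis=2)
            near = (d <= radius_px).any(axis=1)
            if near.any():
                idx = np.flatnonzero(cand)[near]
                member[idx] = True
                changed = True
        assigned |= member
        if member.sum() < min_size:
            continue
        pm = np.zeros((H, W), dtype=bool)
        pm[rows[member], cols[member]] = True
        centre = coords[member].mean(axis=0) * pixel_size
        roi = ROI(pixel_mask=pm, centre=centre,
                  trace=traces[member].mean(axis=0),
                  rho_threshold_used=float(rho_threshold))
        rois.append(roi)
    return rois


def extract_trace(stack: ImageStack, roi: ROI | np.ndarray) -> np.ndarray:
    """Frame-wise mean over the ROI's pixels."""
    mask = roi.pixel_mask if isinstance(roi, ROI) else np.asarray(roi, dtype=bool)
    if mask.sum() == 0:
        raise InvalidArgumentError("empty ROI mask")
    if mask.shape != stack.data.shape[1:]:
        raise InvalidArgumentError("mask shape does not match stack frames")
    return stack.data[:, mask].mean(axis=1)


def extract_rois(stack: ImageStack, detrend: bool = False,
                 min_size: int = 1) -> tuple[list[ROI], float]:
    """Full extraction pipeline: s.d. image -> dendritic mask -> ρ_threshold
    -> grown ROIs. Returns ``(rois, rho_threshold)``.

    ``detrend`` optionally high-passes pixel traces (0.1 Hz cut-off) before
    correlation; default off (correlations on raw traces).
    """
    work = stack
    if detrend:
        from scipy.signal import butter, filtfilt
        b, a = butter(2, 0.1 / (stack.frame_rate / 2), btype="high")
        data = filtfilt(b, a, stack.data, axis=0)
        work = ImageStack(data, stack.frame_rate, stack.pixel_size)
    sd_img = sd_image(work)
    mask = dendritic_pixel_mask(sd_img)
    if not mask.any():
        return [], float("nan")
    rho = correlation_threshold(work, mask)
    rois = grow_rois(work, mask, rho, min_size=min_size)
    if detrend:   # report traces from the raw stack
        for r in rois:
            r.trace = extract_trace(stack, r)
    return rois, rho
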