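"""Receptive-field estimation by evidence optimization (ASD).

The stimulus-response relationship of each dendritic region of interest is
modelled as linear-Gaussian,

    y = kᵀX + ε,   ε ~ N(0, δ²),

where ``y`` is the temporal gradient of the Ca²⁺ trace, ``X`` the lagged
binary dense-noise stimulus and ``k`` the spatio-temporal receptive field
(STRF). ``k`` carries a zero-mean Gaussian prior whose covariance

    C_ij = exp(-ρ - Δ_ij / 2δ)

encodes smoothness (Δ_ij: squared distance between filter coefficients).
Here the prior is structured as a Kronecker product of a 2D spatial and a 1D
temporal kernel with a single shared scale ρ, which keeps the evidence
computation dense-tractable. Hyperparameters (ρ, δ_s, δ_t, δ²) are set by
maximizing the marginal likelihood (evidence) with a derivative-free simplex
search; the STRF is the MAP estimate under the optimized prior.

Downstream, the spatial component of the STRF's singular value
decomposition is upsampled, normalized and contoured (marching squares) at
thresholds {0.60, 0.65, 0.70}; a receptive field passes the quality filter
when its 0.60-level set is a single closed contour with irregularity
Ii = 1 - A_contour/A_convex-hull < 0.1 and area > 1800 µm².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.ndimage import map_coordinates
from scipy.optimize import minimize
from shapely.geometry import Polygon
from skimage.measure import find_contours

from .errors import InvalidArgumentError

JITTER = 1e-6                    # PD safety margin on kernel diagonals
STIM_PIXEL_UM = 30.0             # dense-noise pixel pitch
QUALITY_MIN_AREA_UM2 = 1.8e3     # contour-area cut of the quality filter
QUALITY_MAX_II = 0.1             # irregularity cut of the quality filter


# ---------------------------------------------------------------------------
# Response and design matrix
# ---------------------------------------------------------------------------

def response_gradient(trace, frame_rate: float) -> np.ndarray:
    """Temporal gradient of a Ca²⁺ trace in a.u./s (central differences,
    one-sided at the ends; same length as the input)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 3:
        raise InvalidArgumentError("trace must have at least 3 samples")
    return np.gradient(trace) * frame_rate


def build_design(stimulus, response_times, lag_window=(-1.0, 0.0),
                 n_lags: int | None = None):
    """Lagged, sample-and-hold design matrix.

    The stimulus movie (frames at ``refresh_rate`` starting at t = 0) is
    resampled to the response clock by sample-and-hold; each design row then
    holds the stimulus at lags 0, -Δ, ..., covering ``lag_window`` (default
    -1000...0 ms), where Δ is the response sampling step. The lag count is
    ``ceil(window · response_rate)`` (e.g. 32 at 31.25 Hz). Responses earlier
    than stimulus start + window are trimmed with a warning.

    Returns ``(X, kept)`` where ``X`` has one column per (pixel, lag) in
    pixel-major order and ``kept`` indexes the surviving response samples.
    """
    frames = np.asarray(stimulus.frames, dtype=float)
    refresh = float(stimulus.refresh_rate)
    t = np.asarray(response_times, dtype=float)
    if t.size < 2:
        raise InvalidArgumentError("need at least 2 response samples")
    dt = float(np.median(np.diff(t)))
    window = float(lag_window[1] - lag_window[0])
    if window <= 0:
        raise InvalidArgumentError("lag window must have positive extent")
    if n_lags is None:
        n_lags = int(np.ceil(window / dt - 1e-9))
    lags = np.arange(n_lags) * dt
    t_min = lags[-1]
    kept = np.flatnonzero(t >= t_min - 1e-9)
    if len(kept) < len(t):
        warnings.warn(f"trimmed {len(t) - len(kept)} response samples that "
                      "predate stimulus start + lag window")
    T_s, H, W = frames.shape
    flat = frames.reshape(T_s, H * W)
    n = len(kept)
    X = np.empty((n, H * W * n_lags))
    for j, lag in enumerate(lags):
        idx = np.clip(np.floor((t[kept] - lag) * refresh + 1e-9).astype(int),
                      0, T_s - 1)
        X[:, j::n_lags] = flat[idx]
    return X, kept


# ---------------------------------------------------------------------------
# Evidence optimization
# ---------------------------------------------------------------------------

@dataclass
class ASDModel:
    """Fitted linear-Gaussian RF model."""

    strf: np.ndarray               # (H, W, n_lags)
    noise_var: float               # δ²
    hyperparams: dict              # rho, delta_s, delta_t
    log_evidence: float
    evidence_path: np.ndarray      # best-so-far evidence at accepted steps
    converged: bool
    grid_shape: tuple
    n_lags: int

    def spatial_lag_matrix(self) -> np.ndarray:
        H, W = self.grid_shape
        return self.strf.reshape(H * W, self.n_lags)


def _sq_dist_grid(H: int, W: int) -> np.ndarray:
    r, c = np.unravel_index(np.arange(H * W), (H, W))
    return (r[:, None] - r[None, :]) ** 2 + (c[:, None] - c[None, :]) ** 2


def _kernels(H, W, n_lags, delta_s, delta_t, _cache={}):
    key = (H, W, n_lags)
    if key not in _cache:
        lag = np.arange(n_lags, dtype=float)
        _cache[key] = (_sq_dist_grid(H, W), (lag[:, None] - lag[None, :]) ** 2)
    Ds, Dt = _cache[key]
    Ks = np.exp(-Ds / (2.0 * delta_s)) + JITTER * np.eye(len(Ds))
    Kt = np.exp(-Dt / (2.0 * delta_t)) + JITTER * np.eye(n_lags)
    return Ks, Kt


class _Evidence:
    """Marginal-likelihood evaluator with precomputed sufficient statistics.

    Works in weight space via the determinant lemma / Woodbury identity:
    with A = C⁻¹ + XᵀX/δ²,
    log|Σ| = n log δ² + log|C| + log|A| and
    yᵀΣ⁻¹y = yᵀy/δ² - bᵀA⁻¹b/δ⁴ (b = Xᵀy).
    """

    def __init__(self, X, y, grid_shape, n_lags):
        self.S = X.T @ X
        self.b = X.T @ y
        self.yty = float(y @ y)
        self.n = len(y)
        self.p = X.shape[1]
        self.H, self.W = grid_shape
        self.n_lags = n_lags
        self.var_y = float(np.var(y)) or 1.0

    def _prior(self, rho, delta_s, delta_t):
        Ks, Kt = _kernels(self.H, self.W, self.n_lags, delta_s, delta_t)
        cs, low_s = cho_factor(Ks, lower=True)
        ct, low_t = cho_factor(Kt, lower=True)
        logdet_C = (-rho * self.p
                    + self.n_lags * 2 * np.log(np.diag(cs)).sum()
                    + (self.p // self.n_lags) * 2 * np.log(np.diag(ct)).sum())
        Ks_inv = cho_solve((cs, low_s), np.eye(len(Ks)))
        Kt_inv = cho_solve((ct, low_t), np.eye(self.n_lags))
        C_inv = np.exp(rho) * np.kron(Ks_inv, Kt_inv)
        return C_inv, logdet_C

    def __call__(self, theta, want_map=False):
        rho_t, log_ds, log_dt, log_nv = theta
        rho = rho_t - np.log(self.var_y)
        delta_s, delta_t = np.exp(log_ds), np.exp(log_dt)
        noise_var = np.exp(log_nv) * self.var_y
        try:
            C_inv, logdet_C = self._prior(rho, delta_s, delta_t)
            A = C_inv + self.S / noise_var
            ca, low = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            return (-np.inf, None, None) if want_map else -np.inf
        logdet_A = 2 * np.log(np.diag(ca)).sum()
        Ainv_b = cho_solve((ca, low), self.b)
        quad = self.yty / noise_var - float(self.b @ Ainv_b) / noise_var ** 2
        logdet_sigma = self.n * np.log(noise_var) + logdet_C + logdet_A
        logev = -0.5 * (self.n * np.log(2 * np.pi) + logdet_sigma + quad)
        if not np.isfinite(logev):
            return (-np.inf, None, None) if want_map else -np.inf
        if want_map:
            return logev, Ainv_b / noise_var, noise_var
        return logev


def asd_fit(X, y, grid_shape, n_lags: int, init=None, tol: float = 1e-5,
            max_iter: int = 200) -> ASDModel:
    """Fit the ASD model: optimize (ρ, δ_s, δ_t, δ²) by evidence maximization
    (Nelder–Mead over log-parameters) and return the MAP STRF.

    Scale and noise variance are parametrized relative to ``var(y)``, which
    makes the fit exactly equivariant under rescaling of the response.
    Proposals with non-positive-definite covariance are rejected. If the
    simplex does not converge within ``max_iter`` iterations the best model
    found is returned with ``converged=False``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise InvalidArgumentError("X and y must be finite")
    if X.shape[0] != len(y):
        raise InvalidArgumentError("X rows must match response length")
    H, W = grid_shape
    if X.shape[1] != H * W * n_lags:
        raise InvalidArgumentError("X columns must equal H*W*n_lags")
    if X.shape[0] < X.shape[1]:
        warnings.warn("fewer samples than filter coefficients; the estimate "
                      "relies heavily on the smoothness prior")
    ev = _Evidence(X, y, grid_shape, n_lags)
    if np.allclose(y, 0):
        # no response: evidence is maximized by a zero filter
        strf = np.zeros((H, W, n_lags))
        return ASDModel(strf, ev.var_y, dict(rho=0.0, delta_s=1.0, delta_t=1.0),
                        -np.inf, np.array([]), True, (H, W), n_lags)
    x0 = np.asarray(init if init is not None else [1.0, 0.0, 0.0, 0.0], float)
    path = []

    def objective(theta):
        logev = ev(theta)
        if not path or logev > path[-1]:
            path.append(logev)
        return -logev

    f0 = abs(ev(x0))
    res = minimize(objective, x0, method="Nelder-Mead",
                   options=dict(maxiter=max_iter,
                                fatol=tol * max(1.0, f0),
                                xatol=1e-3))
    logev, k_map, noise_var = ev(res.x, want_map=True)
    if k_map is None:   # best point degenerate; fall back to init
        logev, k_map, noise_var = ev(x0, want_map=True)
    strf = k_map.reshape(H * W, n_lags).reshape(H, W, n_lags)
    rho = res.x[0] - np.log(ev.var_y)
    hyper = dict(rho=float(rho), delta_s=float(np.exp(res.x[1])),
                 delta_t=float(np.exp(res.x[2])))
    return ASDModel(strf, float(noise_var), hyper, float(logev),
                    np.asarray(path), bool(res.success), (H, W), n_lags)


def asd_map(X, y, grid_shape, n_lags, rho, delta_s, delta_t, noise_var):
    """MAP STRF under *fixed* hyperparameters (no evidence optimization).

    In the zero-smoothness limit (δ_s, δ_t -> 0) the prior collapses to
    exp(-ρ)·I and this equals ridge regression with penalty δ²·exp(ρ)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    H, W = grid_shape
    Ks, Kt = _kernels(H, W, n_lags, delta_s, delta_t)
    C_inv = np.exp(rho) * np.kron(np.linalg.inv(Ks), np.linalg.inv(Kt))
    A = C_inv + (X.T @ X) / noise_var
    k = np.linalg.solve(A, X.T @ y) / noise_var
    return k.reshape(H, W, n_lags)


# ---------------------------------------------------------------------------
# SVD spatial map, contours, quality
# ---------------------------------------------------------------------------

@dataclass
class SpatialRF:
    """Spatial component of the STRF's SVD."""

    map: np.ndarray                # (H, W), signed
    temporal: np.ndarray           # (n_lags,), scaled first right vector
    svd_sign: int
    upsample_factor: int = 10
    pixel_size: float = STIM_PIXEL_UM
    upsampled_map: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.upsampled_map is None:
            # bicubic upsampling on a grid with pitch exactly 1/factor pixel,
            # endpoints aligned with the original pixel centres
            H, W = self.map.shape
            f = self.upsample_factor
            r = np.arange((H - 1) * f + 1) / f
            c = np.arange((W - 1) * f + 1) / f
            rr, cc = np.meshgrid(r, c, indexing="ij")
            up = map_coordinates(self.map, [rr, cc], order=3)
            lo, hi = up.min(), up.max()
            if hi > lo:
                up = (up - lo) / (hi - lo)
            else:
                up = np.zeros_like(up)
            self.upsampled_map = up


def svd_spatial_map(strf: np.ndarray, upsample_factor: int = 10,
                    pixel_size: float = STIM_PIXEL_UM) -> SpatialRF:
    """First spatial singular vector of the (space × lag) STRF, signed so the
    spatial extremum is positive (the matching temporal kernel keeps the
    overall product unchanged)."""
    strf = np.asarray(strf, dtype=float)
    if np.allclose(strf, 0):
        raise InvalidArgumentError("all-zero STRF has no spatial map")
    H, W, n_lags = strf.shape
    M = strf.reshape(H * W, n_lags)
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    spatial = u[:, 0]
    temporal = s[0] * vt[0]
    sign = 1 if spatial[np.argmax(np.abs(spatial))] >= 0 else -1
    return SpatialRF(map=(sign * spatial).reshape(H, W),
                     temporal=sign * temporal, svd_sign=sign,
                     upsample_factor=upsample_factor, pixel_size=pixel_size)


@dataclass
class RFContour:
    """A closed iso-contour of the normalized spatial RF map."""

    polygon: np.ndarray           # (n, 2) closed vertex list, µm (x, y)
    threshold_level: float
    area: float                   # µm²
    centre: np.ndarray            # geometric (polygon) centroid, µm
    irregularity: float


def _grid_to_um(contour_rc: np.ndarray, shape_up, upsample: int,
                pixel_size: float) -> np.ndarray:
    """Map marching-squares (row, col) coordinates on the upsampled grid to
    stimulus-centred µm with x right / y up."""
    Hu, Wu = shape_up
    pitch = pixel_size / upsample
    x = (contour_rc[:, 1] - (Wu - 1) / 2.0) * pitch
    y = ((Hu - 1) / 2.0 - contour_rc[:, 0]) * pitch
    return np.column_stack([x, y])


def extract_contours(spatial_rf: SpatialRF,
                     thresholds=(0.60, 0.65, 0.70)) -> dict[float, list[RFContour]]:
    """Closed marching-squares iso-contours of the upsampled, normalized map
    at each threshold. Contours touching the map border (not closed) are
    discarded. Returns ``{threshold: [RFContour, ...]}``."""
    out: dict[float, list[RFContour]] = {}
    up = spatial_rf.upsampled_map
    for thr in thresholds:
        if not (0.0 < thr < 1.0):
            raise InvalidArgumentError("contour thresholds must lie in (0, 1)")
        found = find_contours(up, thr)
        contours = []
        for c in found:
            if not np.allclose(c[0], c[-1]):
                continue
            poly_um = _grid_to_um(c, up.shape, spatial_rf.upsample_factor,
                                  spatial_rf.pixel_size)
            shp = Polygon(poly_um)
            if not shp.is_valid or shp.area <= 0:
                continue
            contours.append(RFContour(
                polygon=poly_um, threshold_level=float(thr),
                area=float(shp.area),
                centre=np.array(shp.centroid.coords[0]),
                irregularity=irregularity_index(poly_um),
            ))
        out[float(thr)] = contours
    return out


def irregularity_index(polygon) -> float:
    """Ii = 1 - A_contour / A_convex-hull of the contour polygon.

    Zero for convex outlines; approaches 1 for deeply indented ones."""
    if isinstance(polygon, RFContour):
        polygon = polygon.polygon
    shp = Polygon(np.asarray(polygon, dtype=float))
    if not shp.is_valid or shp.area <= 0:
        raise InvalidArgumentError("degenerate polygon")
    hull = shp.convex_hull
    if hull.area <= 0:
        raise InvalidArgumentError("degenerate polygon (zero-area hull)")
    return float(1.0 - shp.area / hull.area)


@dataclass
class QualityReport:
    passed: bool
    reasons: list[str]
    n_contours: int
    area: float | None = None
    irregularity: float | None = None


def rf_quality_filter(contours_at_060: list[RFContour],
                      min_area: float = QUALITY_MIN_AREA_UM2,
                      max_irregularity: float = QUALITY_MAX_II) -> QualityReport:
    """Quality gate: exactly one closed 0.60-contour, Ii < 0.1 and
    A_contour > 1800 µm²."""
    reasons = []
    n = len(contours_at_060)
    if n == 0:
        return QualityReport(False, ["no closed contour"], 0)
    if n > 1:
        return QualityReport(False, ["multiple regions"], n)
    c = contours_at_060[0]
    if c.irregularity >= max_irregularity:
        reasons.append("too irregular")
    if c.area <= min_area:
        reasons.append("too small")
    return QualityReport(not reasons, reasons, 1, c.area, c.irregularity)
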