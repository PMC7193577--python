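"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study's recording conditions: a 20 × 15 pixel
binary dense-noise movie (30 µm pixels, 5 Hz, balanced per-pixel sequences)
drives planted Gaussian spatio-temporal receptive fields; dendritic Ca²⁺
movies are rendered at 31.25 Hz with i.i.d. Gaussian pixel noise; chirp
trace sets share a mean response across repetitions with controllable SNR;
parametric skeletons realize target morphological parameters drawn from
reference Off-type specifications; and current-injection experiments produce
somatic spikes with distance-attenuated dendritic Ca²⁺ responses.

Everything is deterministic under a seed, and every generator returns its
ground truth so recovery can be tested quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import morphology as morph
from .errors import GenerationFailureError, InvalidArgumentError
from .io import ImageStack
from .morphology import ChATFrame, Skeleton

STIM_PIXEL_UM = 30.0
STIM_COLS = 20
STIM_ROWS = 15
STIM_REFRESH_HZ = 5.0
MOVIE_RATE_HZ = 31.25
CA_TAU_S = 0.200        # mono-exponential Ca indicator decay


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

@dataclass
class DenseNoiseStimulus:
    """Binary dense-noise movie; ``frames`` is (T, rows, cols)."""

    frames: np.ndarray
    pixel_size: float = STIM_PIXEL_UM
    refresh_rate: float = STIM_REFRESH_HZ
    duration: float = 300.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.refresh_rate

    def pixel_centres_um(self):
        """(rows, cols) µm coordinate grids, stimulus-centred, x right/y up."""
        rows, cols = self.frames.shape[1:]
        x = (np.arange(cols) - (cols - 1) / 2.0) * self.pixel_size
        y = ((rows - 1) / 2.0 - np.arange(rows)) * self.pixel_size
        return np.meshgrid(x, y)


def gen_dense_noise(cols: int = STIM_COLS, rows: int = STIM_ROWS,
                    pixel_size: float = STIM_PIXEL_UM,
                    refresh_rate: float = STIM_REFRESH_HZ,
                    duration: float = 300.0, seed: int = 0) -> DenseNoiseStimulus:
    """Balanced binary dense noise.

    Each pixel shows an independent random sequence containing an equal
    number of 0s and 1s (odd frame counts leave a surplus of one, with the
    surplus value chosen at random), realized as a seeded permutation.
    """
    if cols <= 0 or rows <= 0 or duration <= 0 or refresh_rate <= 0:
        raise InvalidArgumentError("all dimensions must be positive")
    n = int(round(duration * refresh_rate))
    if n < 1:
        raise InvalidArgumentError("duration too short for a single frame")
    rng = np.random.default_rng(seed)
    base = np.zeros((rows * cols, n), dtype=np.uint8)
    base[:, : n // 2] = 1
    if n % 2:
        base[:, n // 2] = rng.integers(0, 2, size=rows * cols)
    frames = rng.permuted(base, axis=1).T.reshape(n, rows, cols)
    return DenseNoiseStimulus(frames, pixel_size, refresh_rate, duration, seed)


@dataclass
class ChirpStimulus:
    """Step + frequency sweep + contrast ramp, intensity in [0, 1]."""

    intensity: np.ndarray
    sample_rate: float
    aperture: str                      # 'local' (100 µm) | 'full' (800×600 µm)
    segment_markers: dict              # step_on/step_off/sweep/contrast times (s)
    aperture_um: float

    def times(self) -> np.ndarray:
        return np.arange(len(self.intensity)) / self.sample_rate


def gen_chirp(aperture: str = "full", sample_rate: float = 500.0,
              contrast: float = 1.0) -> ChirpStimulus:
    """The chirp: 3-s bright step, an accelerating 0.5–8 Hz sinusoid and a
    contrast-ramp sinusoid around a 0.5 background, in that order.

    ``contrast`` scales all modulations (0 gives a constant background).
    """
    f_max = 8.0
    if sample_rate < 2 * f_max:
        raise InvalidArgumentError("sample rate must resolve the 8 Hz sweep")
    if aperture not in ("full", "local"):
        raise InvalidArgumentError("aperture must be 'full' or 'local'")
    # the 6-s lead-in provides the 2500-sample (5 s at 500 Hz) baseline used
    # by the preprocessing and window-detection conventions
    markers = {"step_on": 6.0, "step_off": 9.0, "sweep": (12.0, 20.0),
               "contrast": (22.0, 30.0), "end": 32.0}
    t = np.arange(int(round(markers["end"] * sample_rate))) / sample_rate
    out = np.full_like(t, 0.5)
    step = (t >= markers["step_on"]) & (t < markers["step_off"])
    out[step] += 0.5 * contrast
    s0, s1 = markers["sweep"]
    seg = (t >= s0) & (t < s1)
    ts = t[seg] - s0
    f0, f1 = 0.5, f_max
    phase = 2 * np.pi * (f0 * ts + (f1 - f0) * ts ** 2 / (2 * (s1 - s0)))
    out[seg] += 0.5 * contrast * np.sin(phase)
    c0, c1 = markers["contrast"]
    seg = (t >= c0) & (t < c1)
    tc = t[seg] - c0
    ramp = tc / (c1 - c0)
    out[seg] += 0.5 * contrast * ramp * np.sin(2 * np.pi * 2.0 * tc)
    return ChirpStimulus(np.clip(out, 0.0, 1.0), sample_rate, aperture,
                         markers, 100.0 if aperture == "local" else 800.0)


# ---------------------------------------------------------------------------
# Ground-truth receptive fields and Ca²⁺ movies
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthRF:
    """A planted separable Gaussian spatio-temporal RF."""

    centre: np.ndarray            # (x, y) µm, stimulus-centred
    sigma: np.ndarray             # (σx, σy) µm
    amplitude: float = 1.0
    polarity: str = "Off"
    temporal_kernel: np.ndarray = field(
        default_factory=lambda: np.array([0.9, 0.5, -0.3, -0.1, 0.0]))
    kernel_dt: float = 1.0 / STIM_REFRESH_HZ   # lag step of the kernel, s

    def __post_init__(self):
        self.centre = np.asarray(self.centre, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise InvalidArgumentError("RF widths must be positive")

    def spatial_map(self, rows: int = STIM_ROWS, cols: int = STIM_COLS,
                    pixel_size: float = STIM_PIXEL_UM) -> np.ndarray:
        x = (np.arange(cols) - (cols - 1) / 2.0) * pixel_size
        y = ((rows - 1) / 2.0 - np.arange(rows)) * pixel_size
        gx = np.exp(-0.5 * ((x - self.centre[0]) / self.sigma[0]) ** 2)
        gy = np.exp(-0.5 * ((y - self.centre[1]) / self.sigma[1]) ** 2)
        sign = -1.0 if self.polarity == "Off" else 1.0
        return sign * self.amplitude * np.outer(gy, gx)

    def strf(self, rows: int = STIM_ROWS, cols: int = STIM_COLS,
             pixel_size: float = STIM_PIXEL_UM) -> np.ndarray:
        return self.spatial_map(rows, cols, pixel_size)[..., None] * \
            self.temporal_kernel[None, None, :]


def rf_drive(stimulus: DenseNoiseStimulus, rf: GroundTruthRF) -> np.ndarray:
    """Linear drive of an RF at the stimulus refresh rate: the RF-projected,
    zero-mean stimulus convolved with the temporal kernel (lag 0 = current
    frame)."""
    w = rf.spatial_map(*stimulus.frames.shape[1:], stimulus.pixel_size)
    proj = (stimulus.frames.reshape(stimulus.n_frames, -1) - 0.5) @ w.ravel() * 2.0
    k = rf.temporal_kernel
    drive = np.zeros(stimulus.n_frames)
    for lag, kv in enumerate(k):
        if kv == 0:
            continue
        drive[lag:] += kv * proj[: stimulus.n_frames - lag or None]
    return drive


def ca_trace_from_drive(drive: np.ndarray, refresh_rate: float,
                        frame_rate: float = MOVIE_RATE_HZ,
                        tau: float = CA_TAU_S) -> np.ndarray:
    """Render a Ca²⁺ trace whose temporal gradient is linear in the drive.

    The drive (interpreted as instantaneous rate) is sample-and-hold
    upsampled to the imaging rate and passed through a mono-exponential
    indicator: dCa/dt = rate - Ca/τ (forward Euler at the imaging rate)."""
    n_out = int(round(len(drive) / refresh_rate * frame_rate))
    t = np.arange(n_out) / frame_rate
    idx = np.clip((t * refresh_rate).astype(int), 0, len(drive) - 1)
    rate = drive[idx]
    dt = 1.0 / frame_rate
    ca = np.zeros(n_out)
    for k in range(1, n_out):
        ca[k] = ca[k - 1] + dt * (rate[k - 1] - ca[k - 1] / tau)
    return ca


@dataclass
class SyntheticRecording:
    """A rendered dendritic Ca²⁺ movie plus its ground truth."""

    stack: ImageStack
    planted_rois: list               # boolean H×W masks
    planted_traces: np.ndarray       # (n_rois, T), noiseless, unit s.d.
    rf_truth: list                   # GroundTruthRF per ROI
    roi_nodes: np.ndarray            # skeleton node index per ROI
    noise_sigma: float
    seed: int


def _roi_disc(shape, centre_rc, radius_px: float) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - centre_rc[0]) ** 2 + (cc - centre_rc[1]) ** 2 <= radius_px ** 2


def make_rf_family(profile: str, skeleton: Skeleton,
                   sigma0_um: float = 60.0):
    """RF assignment rule for planted ROIs.

    'local': RF centred on the ROI's own dendritic position, with size
    shrinking with dendritic distance from the soma (tOff-alpha-like);
    'global': all RFs centred near the arbour's centre of mass with a common
    large size (tOff-mini-like).
    """
    if profile not in ("local", "global"):
        raise InvalidArgumentError("profile must be 'local' or 'global'")
    e = skeleton.edges()
    lengths = skeleton.edge_lengths()
    mid = 0.5 * (skeleton.xyz[e[:, 0], :2] + skeleton.xyz[e[:, 1], :2])
    arbour_centre = (mid * lengths[:, None]).sum(axis=0) / lengths.sum()
    max_r = max(np.linalg.norm(skeleton.xyz[:, :2] - skeleton.soma_xyz[:2],
                               axis=1).max(), 1.0)

    def assign(node_index: int, dendritic_distance: float) -> GroundTruthRF:
        pos = skeleton.xyz[node_index, :2]
        if profile == "global":
            return GroundTruthRF(centre=arbour_centre,
                                 sigma=np.array([1.5, 1.5]) * sigma0_um)
        shrink = 1.0 - 0.5 * min(dendritic_distance / max_r, 1.0)
        return GroundTruthRF(centre=pos, sigma=np.array([1.0, 1.0]) *
                             sigma0_um * shrink)

    return assign


def gen_ca_movie(stimulus: DenseNoiseStimulus, skeleton: Skeleton,
                 rf_family="local", noise_sigma: float = 0.2, seed: int = 0,
                 n_rois: int = 5, field_shape=(16, 64), pixel_size: float = 1.0,
                 frame_rate: float = MOVIE_RATE_HZ) -> SyntheticRecording:
    """Render a dendritic recording field with planted ROIs.

    ``n_rois`` discs are planted at well-separated pixel positions; each is
    assigned a node along the skeleton (spread over dendritic distance) and
    an RF from ``rf_family`` ('local', 'global', or a callable
    ``(node_index, dendritic_distance) -> GroundTruthRF``). Pixel traces are
    the ROI's noiseless Ca²⁺ trace (unit s.d.) plus i.i.d. Gaussian noise of
    s.d. ``noise_sigma``; background pixels are pure noise. The movie SNR is
    therefore 1/``noise_sigma``.
    """
    if isinstance(rf_family, str):
        rf_family = make_rf_family(rf_family, skeleton)
    # skeleton must fit the stimulus extent
    ext_x = stimulus.frames.shape[2] * stimulus.pixel_size / 2.0
    ext_y = stimulus.frames.shape[1] * stimulus.pixel_size / 2.0
    if (np.abs(skeleton.xyz[:, 0]).max() > ext_x or
            np.abs(skeleton.xyz[:, 1]).max() > ext_y):
        raise InvalidArgumentError("skeleton extends beyond the stimulus area")
    rng = np.random.default_rng(seed)
    H, W = field_shape
    # pick ROI nodes spread over dendritic distance to the soma
    g = skeleton.graph()
    import networkx as nx
    dist = nx.single_source_dijkstra_path_length(g, skeleton.root_index)
    nodes = np.array(sorted(dist, key=dist.get))
    picks = nodes[np.linspace(len(nodes) // 4, len(nodes) - 1, n_rois).astype(int)]
    # well-separated pixel placements on a grid
    radius_px = 1.6 / pixel_size
    margin = int(np.ceil(radius_px)) + 1
    xs = np.linspace(margin, W - 1 - margin, n_rois)
    ys = (margin + (np.arange(n_rois) % 2) * (H - 1 - 2 * margin))
    masks, truths = [], []
    T = int(round(stimulus.duration * frame_rate))
    traces = np.zeros((n_rois, T))
    for i, node in enumerate(picks):
        mask = _roi_disc(field_shape, (ys[i], xs[i]), radius_px)
        rf = rf_family(int(node), float(dist[int(node)]))
        drive = rf_drive(stimulus, rf)
        ca = ca_trace_from_drive(drive, stimulus.refresh_rate, frame_rate)[:T]
        sd = ca.std(ddof=0)
        if sd > 0:
            ca = ca / sd
        masks.append(mask)
        truths.append(rf)
        traces[i, : len(ca)] = ca
    data = rng.normal(0.0, noise_sigma, size=(T, H, W)) if noise_sigma > 0 \
        else np.zeros((T, H, W))
    for mask, tr in zip(masks, traces):
        data[:, mask] += tr[:, None]
    stack = ImageStack(data, frame_rate, pixel_size)
    return SyntheticRecording(stack, masks, traces, truths,
                              np.asarray(picks, dtype=int),
                              noise_sigma, seed)


# ---------------------------------------------------------------------------
# Chirp trace sets
# ---------------------------------------------------------------------------

def chirp_mean_response(chirp: ChirpStimulus, sample_rate: float = MOVIE_RATE_HZ,
                        transience: float = 0.7) -> np.ndarray:
    """A smooth Off-type mean response to the chirp: rectified luminance
    decrements plus a sustained component, passed through the Ca kernel."""
    t_new = np.arange(int(round(chirp.times()[-1] * sample_rate))) / sample_rate
    inten = np.interp(t_new, chirp.times(), chirp.intensity)
    dec = np.maximum(-np.gradient(inten) * sample_rate, 0.0)
    sustained = np.maximum(0.5 - inten, 0.0)
    drive = dec + (1.0 - transience) * 2.0 * sustained
    dt = 1.0 / sample_rate
    ca = np.zeros_like(drive)
    for k in range(1, len(drive)):
        ca[k] = ca[k - 1] + dt * (drive[k - 1] - ca[k - 1] / CA_TAU_S)
    return ca


def gen_chirp_traceset(chirp: ChirpStimulus, n_reps: int = 5,
                       snr: float = 5.0, seed: int = 0,
                       sample_rate: float = MOVIE_RATE_HZ,
                       mean_response: np.ndarray | None = None):
    """Trial matrix = shared mean response + Gaussian noise with
    s.d. = s.d.(mean)/snr. Returns a temporal_metrics.TraceSet."""
    from .temporal_metrics import TraceSet

    if n_reps < 1:
        raise InvalidArgumentError("need at least one repetition")
    if not (snr > 0):
        raise InvalidArgumentError("snr must be positive")
    rng = np.random.default_rng(seed)
    mean = chirp_mean_response(chirp, sample_rate) if mean_response is None \
        else np.asarray(mean_response, float)
    noise_sd = mean.std(ddof=0) / snr if np.isfinite(snr) else 0.0
    trials = mean[:, None] + rng.normal(0.0, noise_sd, (len(mean), n_reps))
    return TraceSet(trials, sample_rate,
                    stimulus_onset=chirp.segment_markers["step_on"],
                    stimulus_offset=chirp.segment_markers["step_off"])


# ---------------------------------------------------------------------------
# Morphological type specifications and skeleton growth
# ---------------------------------------------------------------------------

@dataclass
class MorphoTypeSpec:
    """Mean ± dispersion of the four morphological parameters of one type.

    The '±' values are used as the per-cell s.d. by default, which keeps the
    four types well separated (the regime recovery tests assume). Setting
    ``pm_is_sem=True`` instead treats them as s.e.m. of the type mean and
    converts to a per-cell s.d. by ×√n, a much broader, overlapping spread.
    Units: ADD and asymmetry a.u. (package scale), area 10³ µm², soma µm².
    """

    type_name: str
    add_mean: float
    add_pm: float
    area_mean: float
    area_pm: float
    asym_mean: float
    asym_pm: float
    soma_mean: float
    soma_pm: float
    n_cells: int
    pm_is_sem: bool = False

    def sd(self, which: str) -> float:
        pm = getattr(self, f"{which}_pm")
        if pm < 0:
            raise InvalidArgumentError("dispersions must be >= 0")
        return pm * np.sqrt(self.n_cells) if self.pm_is_sem else pm


#: reference Off-type specifications (mean ± s.e.m., n per type).
OFF_TYPE_SPECS = {
    "tOff alpha": MorphoTypeSpec("tOff alpha", -2.41, 0.44, 53.2, 2.3,
                                 44.9, 6.3, 322.5, 8.3, 17),
    "tOff mini": MorphoTypeSpec("tOff mini", -5.10, 0.57, 29.7, 1.9,
                                18.9, 4.1, 151.5, 14.8, 5),
    "sOff": MorphoTypeSpec("sOff", 8.58, 1.19, 29.0, 1.5,
                           14.2, 3.7, 204.0, 34.1, 4),
    "F-miniOff": MorphoTypeSpec("F-miniOff", 6.77, 0.62, 11.5, 0.6,
                                74.8, 6.2, 102.7, 2.2, 5),
}


def _truncated_normal(rng, mean, sd, n_sigma=2.0):
    """Normal draw re-sampled into mean ± n_sigma·sd (keeps synthetic cells
    within the reported range of their type)."""
    if sd == 0:
        return float(mean)
    for _ in range(100):
        x = rng.normal(mean, sd)
        if abs(x - mean) <= n_sigma * sd:
            return float(x)
    return float(mean)


def sample_morpho_params(spec: MorphoTypeSpec, rng) -> dict:
    """Draw one cell's target parameters from a type specification
    (truncated at 2 dispersions around the type mean)."""
    add = float(np.clip(_truncated_normal(rng, spec.add_mean, spec.sd("add")),
                        -0.98 * morph.ADD_SCALE_DEFAULT,
                        0.98 * morph.ADD_SCALE_DEFAULT))
    area = max(_truncated_normal(rng, spec.area_mean, spec.sd("area")) * 1e3, 2e3)
    asym = max(_truncated_normal(rng, spec.asym_mean, spec.sd("asym")), 0.0)
    soma = max(_truncated_normal(rng, spec.soma_mean, spec.sd("soma")), 20.0)
    return {"arbour_density_difference": add, "area": area,
            "asymmetry": asym, "soma_size": soma}


def gen_morpho_table(specs=None, seed: int = 0) -> pd.DataFrame:
    """A reference-cohort: per-cell parameter draws for every type
    (default n = 17/5/4/5), with the planted type label."""
    specs = specs or OFF_TYPE_SPECS
    rng = np.random.default_rng(seed)
    rows = []
    for name, spec in specs.items():
        for _ in range(spec.n_cells):
            row = sample_morpho_params(spec, rng)
            row["planted_type"] = name
            rows.append(row)
    return pd.DataFrame(rows)


Z_GCL, Z_INL = 0.0, 40.0          # IPL axis of generated skeletons, µm
Z_CENTRAL, Z_MARGINAL = 25.0, 35.0  # depths 0.625 (central) and 0.875 (marginal)


def _grow_tree_2d(tips_xy: np.ndarray, step_um: float = 8.0):
    """Nearest-neighbour growth: connect each tip to the closest point of the
    already-built tree (starting from the soma at the origin), inserting
    intermediate nodes every ``step_um``. Returns (xy, parents) with node 0
    the soma."""
    xy = [np.zeros(2)]
    parents = [-1]
    for tip in tips_xy:
        built = np.asarray(xy)
        j = int(np.argmin(np.linalg.norm(built - tip, axis=1)))
        a = built[j]
        L = float(np.linalg.norm(tip - a))
        n_seg = max(1, int(np.ceil(L / step_um)))
        prev = j
        for s in range(1, n_seg + 1):
            p = a + (tip - a) * s / n_seg
            xy.append(p)
            parents.append(prev)
            prev = len(xy) - 1
    return np.asarray(xy), np.asarray(parents)


def _dfs_order(parents) -> list[int]:
    kids: dict[int, list[int]] = {i: [] for i in range(len(parents))}
    for i, p in enumerate(parents):
        if p >= 0:
            kids[p].append(i)
    order, stack = [], [0]
    while stack:
        node = stack.pop()
        if node != 0:
            order.append(node)
        stack.extend(reversed(kids[node]))
    return order


def _depths_for_boundary(n_nodes, order, n_central, f_central):
    z = np.full(n_nodes, Z_MARGINAL)
    z[0] = Z_CENTRAL if f_central >= 0.5 else Z_MARGINAL
    for k, node in enumerate(order):
        z[node] = Z_CENTRAL if k < n_central else Z_MARGINAL
    return z


def _assign_depths(xy, parents, radius, add_target: float, chat: ChATFrame):
    """Assign per-node z (two strata) so that the measured arbour density
    difference matches ``add_target``; the central/marginal boundary index
    along the DFS edge order is found by bisection against the actual
    metric (crossing edges are split at the band boundary, so the prefix
    length alone is biased)."""
    order = _dfs_order(parents)
    f_central = (1.0 + add_target / morph.ADD_SCALE_DEFAULT) / 2.0

    def measured(n_central):
        z = _depths_for_boundary(len(parents), order, n_central, f_central)
        skel = Skeleton(np.arange(1, len(parents) + 1),
                        np.where(parents < 0, -1, parents + 1),
                        np.column_stack([xy, z]), radius,
                        ipl_axis=(Z_GCL, Z_INL))
        return morph.arbour_density_difference(skel, chat), z

    lo, hi = 0, len(order)
    add_lo, z_lo = measured(lo)
    add_hi, z_hi = measured(hi)
    if add_target <= add_lo:
        return z_lo
    if add_target >= add_hi:
        return z_hi
    best = None
    while hi - lo > 1:
        mid = (lo + hi) // 2
        add_mid, z_mid = measured(mid)
        if best is None or abs(add_mid - add_target) < best[0]:
            best = (abs(add_mid - add_target), z_mid)
        if add_mid < add_target:
            lo = mid
        else:
            hi = mid
    return best[1]


def gen_skeleton(type_spec: MorphoTypeSpec, seed: int = 0,
                 targets: dict | None = None, n_tips: int = 40,
                 max_retries: int = 4) -> Skeleton:
    """Grow a skeleton whose morphological parameters match a type spec.

    Target values are drawn from ``type_spec`` (or supplied); the planar tree is
    grown by nearest-neighbour attachment of tips filling a disc whose
    radius and centre offset are calibrated iteratively against the measured
    area and asymmetry, and depths are assigned to match the target arbour
    density difference. Raises GenerationFailureError when the targets stay
    unreachable after ``max_retries`` fresh growth attempts (e.g. asymmetry
    far exceeding the arbour radius).
    """
    rng = np.random.default_rng(seed)
    tgt = targets or sample_morpho_params(type_spec, rng)
    area_t = tgt["area"]
    asym_t = tgt["asymmetry"]
    add_t = tgt["arbour_density_difference"]
    soma_r = np.sqrt(tgt["soma_size"] / np.pi)
    chat = ChATFrame()
    for attempt in range(max_retries):
        R = np.sqrt(area_t / np.pi)
        if asym_t > 2.0 * R:
            raise GenerationFailureError(
                f"asymmetry target {asym_t:.0f} µm exceeds arbour radius {R:.0f} µm")
        u = rng.standard_normal((n_tips, 2))
        u = u / np.linalg.norm(u, axis=1, keepdims=True)
        u = u * np.sqrt(rng.uniform(0.05, 1.0, n_tips))[:, None]
        c = np.array([asym_t, 0.0])
        ok = False
        for _ in range(8):
            tips = c + R * u
            xy, parents = _grow_tree_2d(tips)
            radius = np.full(len(parents), 0.5)
            radius[0] = soma_r
            z = _assign_depths(xy, parents, radius, add_t, chat)
            skel = Skeleton(np.arange(1, len(parents) + 1),
                            np.where(parents < 0, -1, parents + 1),
                            np.column_stack([xy, z]), radius,
                            ipl_axis=(Z_GCL, Z_INL))
            area_m = morph.arbour_area(skel)
            asym_m = morph.asymmetry(skel)
            # vector/scale corrections toward the targets
            e = skel.edges()
            L = skel.edge_lengths()
            mid = 0.5 * (skel.xyz[e[:, 0], :2] + skel.xyz[e[:, 1], :2])
            centroid = (mid * L[:, None]).sum(axis=0) / L.sum()
            if (abs(area_m - area_t) < 0.03 * area_t
                    and abs(asym_m - asym_t) < max(0.03 * asym_t, 1.5)):
                ok = True
                break
            R *= np.sqrt(area_t / area_m)
            c = c + (np.array([asym_t, 0.0]) - centroid)
        if ok:
            return skel
    raise GenerationFailureError(
        f"could not realize morphology targets for {type_spec.type_name} "
        f"after {max_retries} attempts")


# ---------------------------------------------------------------------------
# Current-injection experiments
# ---------------------------------------------------------------------------

@dataclass
class BackpropCellProfile:
    """Phenomenological backpropagation strength of one cell type."""

    name: str = "strong-backprop"
    gain_hz_per_na: float = 60.0      # spike rate above rheobase
    rheobase_na: float = 0.05
    slope_proximal: float = 3.03      # Ca AUC (baseline-s.d. units) per spike
    slope_distal: float = 1.40
    d_proximal_um: float = 25.0
    d_distal_um: float = 150.0
    noise_sd: float = 0.0             # Ca trace noise, baseline-s.d. units
    jitter: bool = False              # Poisson spike-count jitter

    def slope_at(self, distance_um: float) -> float:
        t = np.clip((distance_um - self.d_proximal_um)
                    / (self.d_distal_um - self.d_proximal_um), 0.0, 1.0)
        return float(self.slope_proximal +
                     t * (self.slope_distal - self.slope_proximal))


STRONG_BACKPROP = BackpropCellProfile("strong-backprop", slope_proximal=3.03,
                                      slope_distal=1.40)
WEAK_BACKPROP = BackpropCellProfile("weak-backprop", slope_proximal=0.44,
                                    slope_distal=0.24)


def gen_current_injection(cell_profile: BackpropCellProfile, steps,
                          seed: int = 0, roi_distances=(25.0, 150.0),
                          n_rois_per_distance: int = 3,
                          v_rate: float = 1e4, ca_rate: float = MOVIE_RATE_HZ):
    """Simulate a somatic current-step experiment.

    500-ms steps of the given amplitudes (nA) are injected with 12 s
    spacing. The somatic voltage (10 kHz) carries spike waveforms whose
    count follows rate = gain·(I − rheobase)⁺ (Poisson jitter optional); each
    dendritic ROI's Ca²⁺ trace carries, per step, a response whose
    area under the curve equals slope(distance) × spike count (in
    baseline-s.d. units) plus optional noise.

    Returns ``(voltage, ca_records, step_onsets, spike_counts)`` where
    ``ca_records`` is a list of dicts compatible with
    temporal_metrics.BackpropExperiment.
    """
    steps = np.atleast_1d(np.asarray(steps, dtype=float))
    if steps.size == 0:
        raise InvalidArgumentError("need at least one current step")
    if np.any((steps < 0) | (steps > 0.5)):
        raise InvalidArgumentError("step amplitudes must lie in [0, 0.5] nA")
    rng = np.random.default_rng(seed)
    spacing, step_dur, auc_win = 12.0, 0.5, 1.6
    onsets = 6.0 + spacing * np.arange(len(steps))
    total_t = onsets[-1] + spacing
    nv = int(round(total_t * v_rate))
    voltage = np.full(nv, -65.0)
    spike_counts = []
    spike_width = int(round(0.002 * v_rate))
    wave = 85.0 * np.hanning(spike_width)           # -65 -> +20 mV
    for onset, amp in zip(onsets, steps):
        rate = cell_profile.gain_hz_per_na * max(amp - cell_profile.rheobase_na, 0.0)
        mean_count = rate * step_dur
        count = int(rng.poisson(mean_count)) if cell_profile.jitter \
            else int(round(mean_count))
        spike_counts.append(count)
        if count:
            times = onset + (np.arange(count) + 0.5) * step_dur / count
            for ts in times:
                i0 = int(round(ts * v_rate))
                voltage[i0:i0 + spike_width] = np.maximum(
                    voltage[i0:i0 + spike_width], -65.0 + wave[: nv - i0])
    nc = int(round(total_t * ca_rate))
    dt = 1.0 / ca_rate
    n_win = int(round(auc_win * ca_rate))
    ca_records = []
    for d in np.atleast_1d(roi_distances):
        slope = cell_profile.slope_at(float(d))
        for _ in range(n_rois_per_distance):
            tr = np.zeros(nc)
            for onset, count in zip(onsets, spike_counts):
                i0 = int(round(onset * ca_rate))
                # flat pulse whose trapezoidal integral is slope × count
                h = slope * count / ((n_win - 1) * dt)
                tr[i0:i0 + n_win] = h
            if cell_profile.noise_sd > 0:
                # scale the signal by the noise s.d. so that the baseline-s.d.
                # normalization downstream returns AUCs on the planted scale
                s = cell_profile.noise_sd
                tr = s * tr + rng.normal(0.0, s, nc)
            ca_records.append({"trace": tr, "sample_rate": ca_rate,
                               "distance_um": float(d)})
    return voltage, ca_records, onsets, np.asarray(spike_counts)
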