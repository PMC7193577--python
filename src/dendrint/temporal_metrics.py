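"""Chirp-response preprocessing and temporal response statistics.

Implements the trial-based quality index Qi, pairwise trace correlation,
response-window detection by binomial smoothing and baseline-s.d.
thresholding, the transience index Ti and polarity index POi computed from
the step part of the chirp stimulus, and the current-injection
backpropagation analysis (dendritic Ca²⁺ area-under-curve regressed on
somatic spike count, with slope contrasts between cell types and dendritic
locations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.stats import binom, f as f_dist, studentized_range
import statsmodels.api as sm

from .errors import InvalidArgumentError, UndefinedMetricError

CHIRP_RATE_HZ = 500.0         # preprocessing target rate
BASELINE_SAMPLES = 2500       # pre-onset samples defining the baseline (5 s at 500 Hz)
BINOMIAL_PASSES = 3000        # smoothing order for window detection
POLARITY_WINDOW_S = 3.0       # b in the polarity index
AUC_WINDOW_S = 1.6            # Ca AUC / spike-count window after step onset
SPIKE_THRESHOLD_MV = -10.0


@dataclass
class TraceSet:
    """Repetition-aligned response traces.

    ``trials`` is a T×R array (time samples × repetitions)."""

    trials: np.ndarray
    sample_rate: float
    stimulus_onset: float      # s
    stimulus_offset: float     # s

    def __post_init__(self):
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        if self.trials.ndim != 2:
            raise InvalidArgumentError("trials must be a T×R array")
        if self.trials.shape[1] < 1:
            raise InvalidArgumentError("need at least one repetition")
        if not (0 <= self.stimulus_onset < self.stimulus_offset):
            raise InvalidArgumentError("require 0 <= onset < offset")

    @property
    def n_reps(self) -> int:
        return self.trials.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.trials.shape[0]) / self.sample_rate

    def mean_trace(self) -> np.ndarray:
        return self.trials.mean(axis=1)


def preprocess_chirp(raw: TraceSet, target_rate: float = CHIRP_RATE_HZ,
                     baseline_samples: int = BASELINE_SAMPLES) -> TraceSet:
    """Linearly upsample to 500 Hz, subtract the baseline mean (2500 samples
    before stimulus onset) and divide by the baseline s.d., per repetition.

    Repetitions whose baseline has zero variance are only mean-subtracted
    (division guarded)."""
    if raw.sample_rate > target_rate:
        raise InvalidArgumentError("raw sample rate must be <= target rate")
    t_old = raw.times
    n_new = int(np.round(t_old[-1] * target_rate)) + 1
    t_new = np.arange(n_new) / target_rate
    onset_idx = int(np.floor(raw.stimulus_onset * target_rate))
    if onset_idx < baseline_samples:
        raise InvalidArgumentError(
            f"need {baseline_samples} pre-onset samples at {target_rate} Hz; "
            f"stimulus onset at sample {onset_idx}")
    out = np.empty((n_new, raw.n_reps))
    for r in range(raw.n_reps):
        tr = np.interp(t_new, t_old, raw.trials[:, r])
        base = tr[onset_idx - baseline_samples:onset_idx]
        tr = tr - base.mean()
        sd = base.std(ddof=0)
        if sd > 0:
            tr = tr / sd
        out[:, r] = tr
    return TraceSet(out, target_rate, raw.stimulus_onset, raw.stimulus_offset)


def quality_index(traceset: TraceSet) -> float:
    """Response quality index:

        Qi = Var_t[ mean_r(C) ] / mean_r[ Var_t(C) ]

    the variance over time of the trial mean divided by the trial-average of
    the per-trial time variance. Identical repetitions give Qi = 1;
    independent noise gives Qi ≈ 1/R."""
    C = traceset.trials
    if C.shape[1] < 2:
        raise InvalidArgumentError("Qi needs at least 2 repetitions")
    denom = C.var(axis=0, ddof=0).mean()
    if denom == 0:
        raise UndefinedMetricError("all trials constant: Qi undefined")
    return float(C.mean(axis=1).var(ddof=0) / denom)


def pairwise_correlation(mean_trace_a, mean_trace_b) -> float:
    """Pearson correlation of two mean responses."""
    a = np.asarray(mean_trace_a, float)
    b = np.asarray(mean_trace_b, float)
    if a.shape != b.shape:
        raise InvalidArgumentError("traces must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise UndefinedMetricError("zero-variance trace")
    return float(np.corrcoef(a, b)[0, 1])


def binomial_smooth(trace, passes: int = BINOMIAL_PASSES,
                    literal: bool = False) -> np.ndarray:
    """Binomial smoothing: ``passes`` convolutions with the [1, 2, 1]/4 kernel.

    The default path convolves once with the exact ``passes``-fold composite
    kernel (binomial weights of order ``2·passes``), which is identical to
    iterating by associativity of convolution; ``literal=True`` runs the
    iterative loop instead. Edges use reflect padding. The composite kernel
    is close to a Gaussian with σ = sqrt(passes/2) samples.
    """
    x = np.asarray(trace, dtype=float)
    if literal:
        k = np.array([0.25, 0.5, 0.25])
        for _ in range(passes):
            xp = np.pad(x, 1, mode="reflect")
            x = np.convolve(xp, k, mode="valid")
        return x
    half = min(7 * int(np.ceil(np.sqrt(passes / 2.0))) + 2, passes)
    support = np.arange(-half, half + 1)
    kernel = binom.pmf(support + passes, 2 * passes, 0.5)
    kernel = kernel / kernel.sum()
    xp = np.pad(x, half, mode="reflect")
    return fftconvolve(xp, kernel, mode="valid")


@dataclass
class ResponseWindow:
    """Detected response span relative to a stimulus step."""

    onset: float                  # T_R_onset, s
    offset: float                 # T_R_offset, s
    t_stim_on: float
    t_stim_off: float
    responsive: bool = True

    @property
    def stimulus_duration(self) -> float:
        return self.t_stim_off - self.t_stim_on


def response_window(mean_trace, sample_rate: float, t_stim_on: float,
                    t_stim_off: float, baseline_samples: int = BASELINE_SAMPLES,
                    passes: int = BINOMIAL_PASSES,
                    min_duration_s: float = 0.5) -> ResponseWindow:
    """Detect response onset/offset around a stimulus step.

    The mean trace is binomially smoothed; 2 s.d. of its baseline (the
    ``baseline_samples`` samples before stimulus onset) defines the
    threshold. Onset is the first |trace| threshold crossing after stimulus
    onset, offset the last; a crossing only counts when it is sustained for
    ``min_duration_s`` (default 0.5 s: smoothed-noise excursions above
    2 s.d. are frequent and last up to ~0.4 s, so shorter runs are not
    treated as responses). A trace with no sustained crossing is flagged
    non-responsive.
    """
    sm_trace = binomial_smooth(mean_trace, passes)
    on_idx = int(np.floor(t_stim_on * sample_rate))
    if on_idx < baseline_samples:
        raise InvalidArgumentError("not enough pre-onset samples for a baseline")
    base = sm_trace[on_idx - baseline_samples:on_idx]
    thr = 2.0 * base.std(ddof=0)
    dev = np.abs(sm_trace - base.mean())
    above = dev[on_idx:] > thr
    if thr == 0 or not above.any():
        return ResponseWindow(np.nan, np.nan, t_stim_on, t_stim_off,
                              responsive=False)
    min_run = max(1, int(round(min_duration_s * sample_rate)))
    padded = np.r_[False, above, False].astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    keep = (stops - starts) >= min_run
    if not keep.any():
        return ResponseWindow(np.nan, np.nan, t_stim_on, t_stim_off,
                              responsive=False)
    onset = (on_idx + starts[keep][0]) / sample_rate
    offset = (on_idx + stops[keep][-1] - 1) / sample_rate
    return ResponseWindow(onset, offset, t_stim_on, t_stim_off)


def transience_index(window: ResponseWindow) -> float:
    """Ti = 1 - (T_R_offset - T_R_onset) / T_stimulus, clipped to [0, 1]."""
    if not window.responsive:
        raise InvalidArgumentError("non-responsive window has no Ti")
    dur = window.offset - window.onset
    if dur > window.stimulus_duration:
        warnings.warn("response outlasts the stimulus; Ti clipped to 0")
        return 0.0
    return float(1.0 - dur / window.stimulus_duration)


def polarity_index(mean_trace, window: ResponseWindow, sample_rate: float,
                   b: float = POLARITY_WINDOW_S, passes: int = BINOMIAL_PASSES
                   ) -> float:
    """POi = (Σ_on - Σ_off) / (Σ_on + Σ_off), with Σ_on/Σ_off the sums of the
    response over the ``b`` = 3 s windows after stimulus onset and offset.

    Samples outside the detected response window are zeroed first. The
    smoothed trace is used, consistent with the window detection. Onset-only
    responses give +1, offset-only responses -1."""
    if not window.responsive:
        raise InvalidArgumentError("non-responsive window has no POi")
    r = binomial_smooth(np.asarray(mean_trace, float), passes).copy()
    i0 = int(np.round(window.onset * sample_rate))
    i1 = int(np.round(window.offset * sample_rate))
    r[:i0] = 0.0
    r[i1 + 1:] = 0.0
    nb = int(np.round(b * sample_rate))
    on0 = int(np.round(window.t_stim_on * sample_rate))
    off0 = int(np.round(window.t_stim_off * sample_rate))
    s_on = float(r[on0:on0 + nb].sum())
    s_off = float(r[off0:off0 + nb].sum())
    if s_on + s_off == 0:
        raise UndefinedMetricError("both on and off sums are zero")
    return (s_on - s_off) / (s_on + s_off)


# ---------------------------------------------------------------------------
# Backpropagation (current-injection) analysis
# ---------------------------------------------------------------------------

def spike_count(voltage, sample_rate: float = 1e4, window=None,
                threshold: float = SPIKE_THRESHOLD_MV) -> int:
    """Number of upward threshold crossings (default -10 mV) of a somatic
    voltage trace, optionally restricted to a ``(t_start, t_end)`` window."""
    v = np.asarray(voltage, dtype=float)
    if window is not None:
        i0 = int(np.floor(window[0] * sample_rate))
        i1 = int(np.ceil(window[1] * sample_rate))
        v = v[max(i0, 0):i1]
    if v.size < 2:
        return 0
    above = v >= threshold
    return int(np.count_nonzero(~above[:-1] & above[1:]))


@dataclass
class BackpropExperiment:
    """One simultaneous somatic-voltage / dendritic-Ca²⁺ recording.

    ``ca_traces`` maps a group label (e.g. ``"tOff mini/proximal"``) to a
    list of per-ROI records ``{"trace": array, "sample_rate": Hz,
    "distance_um": float}``. ``voltage`` may also be a list of per-sweep
    traces aligned with ``step_onsets``."""

    voltage: np.ndarray
    v_sample_rate: float
    ca_traces: dict
    step_onsets: np.ndarray           # s, one per current step
    step_amplitudes: np.ndarray       # nA
    baseline_s: float = 5.0           # normalization window at trace start


def ca_auc(trace, sample_rate: float, step_onset: float,
           baseline_s: float = 5.0, auc_window_s: float = AUC_WINDOW_S) -> float:
    """Area under the normalized Ca²⁺ response within 1.6 s of step onset.

    The trace is divided by the s.d. of its first ``baseline_s`` seconds and
    the mean of the 5 s immediately before the step is subtracted; the AUC is
    the trapezoidal integral of the result."""
    x = np.asarray(trace, dtype=float)
    nb = int(np.round(baseline_s * sample_rate))
    sd = x[:nb].std(ddof=0)
    if sd == 0:
        sd = 1.0
    x = x / sd
    i_on = int(np.round(step_onset * sample_rate))
    pre = x[max(i_on - nb, 0):i_on]
    x = x - (pre.mean() if len(pre) else 0.0)
    i_end = i_on + int(np.round(auc_window_s * sample_rate))
    seg = x[i_on:i_end]
    return float(np.trapezoid(seg, dx=1.0 / sample_rate))


@dataclass
class BackpropResult:
    groups: pd.DataFrame          # per-group slope, CI, r², p, n
    pairwise: pd.DataFrame        # Tukey-adjusted slope contrasts
    interaction_F: float
    interaction_p: float
    table: pd.DataFrame           # underlying (group, spikes, auc) rows


def backprop_regression(experiment: BackpropExperiment) -> BackpropResult:
    """Regress dendritic Ca²⁺ AUC on somatic spike count, per group.

    Per group: ordinary least squares slope with 95% CI and r². Across
    groups: F-test of the spike-count × group interaction (equality of
    slopes), with Tukey-adjusted pairwise slope contrasts computed from the
    full interaction model via the studentized range distribution.
    """
    rows = []
    for g, rois in experiment.ca_traces.items():
        for roi in rois:
            for onset in np.atleast_1d(experiment.step_onsets):
                n_sp = spike_count(experiment.voltage,
                                   experiment.v_sample_rate,
                                   window=(onset, onset + AUC_WINDOW_S))
                auc = ca_auc(roi["trace"], roi["sample_rate"], onset,
                             experiment.baseline_s)
                rows.append({"group": g, "spikes": float(n_sp), "auc": auc,
                             "distance_um": roi.get("distance_um", np.nan)})
    table = pd.DataFrame(rows)
    return regress_auc_table(table)


def regress_auc_table(table: pd.DataFrame) -> BackpropResult:
    """Slope statistics from a tidy (group, spikes, auc) table."""
    if table.empty:
        raise InvalidArgumentError("empty backprop table")
    group_stats = []
    for g, sub in table.groupby("group", sort=True):
        if sub["spikes"].nunique() < 2:
            raise InvalidArgumentError(
                f"group {g!r} needs >= 2 distinct spike counts")
        model = sm.OLS(sub["auc"], sm.add_constant(sub["spikes"])).fit()
        ci = model.conf_int().loc["spikes"]
        group_stats.append({
            "group": g, "slope": model.params["spikes"],
            "ci_low": ci[0], "ci_high": ci[1],
            "r2": model.rsquared, "p": model.pvalues["spikes"],
            "n": len(sub),
        })
    groups = pd.DataFrame(group_stats).set_index("group")
    labels = groups.index.tolist()
    k = len(labels)
    if k < 2:
        return BackpropResult(groups, pd.DataFrame(), np.nan, np.nan, table)
    # full interaction model: separate intercept and slope per group
    dummies = pd.get_dummies(table["group"], dtype=float)
    Xf = pd.concat(
        [dummies.rename(columns=lambda c: f"i::{c}"),
         dummies.mul(table["spikes"], axis=0).rename(columns=lambda c: f"s::{c}")],
        axis=1)
    full = sm.OLS(table["auc"], Xf).fit()
    # reduced: common slope
    Xr = pd.concat([dummies.rename(columns=lambda c: f"i::{c}"),
                    table[["spikes"]]], axis=1)
    red = sm.OLS(table["auc"], Xr).fit()
    df_num = k - 1
    df_den = int(full.df_resid)
    F = ((red.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    p_F = float(f_dist.sf(F, df_num, df_den))
    cov = full.cov_params()
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = f"s::{labels[i]}", f"s::{labels[j]}"
            diff = full.params[a] - full.params[b]
            se = np.sqrt(cov.loc[a, a] + cov.loc[b, b] - 2 * cov.loc[a, b])
            q = abs(diff) / (se / np.sqrt(2.0))
            p = float(studentized_range.sf(q, k, df_den))
            pairs.append({"group_a": labels[i], "group_b": labels[j],
                          "slope_diff": diff, "se": se, "p_tukey": p})
    return BackpropResult(groups, pd.DataFrame(pairs), float(F), float(p_F),
                          table)
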