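"""Ball-and-stick multi-compartment model of RGC dendritic signal propagation.

The dendrite is a chain of cylindrical sections, one per branch order, whose
diameter and length follow a branch-order profile (decreasing radius and
lengthening segments for a tOff-alpha-like cell; roughly constant for a
tOff-mini-like cell); a spherical soma caps the proximal end. Each section is
discretized into compartments of at most 7 µm. Membrane voltage follows the
cable equation

    (d / 4 r_a) ∂²V/∂x² = C_m ∂V/∂t + I_ion - I_stim,

with I_ion the sum of Hodgkin–Huxley-type currents in the Fohlmeister–Miller
RGC formulation: fast Na (m³h), Ca (c³), delayed-rectifier K (n⁴), A-type K
(a³h_A), Ca-activated K, and leak. Gating rate functions, the intracellular
Ca pool (shell influx + first-order extrusion) and the Nernst Ca reversal
are exposed as a plain-dict kinetics config so every constant is pinned and
serialisable.

Time stepping is Crank–Nicolson on the (tridiagonal) voltage system with
Rush–Larsen exponential gating updates; spatial coupling uses axial
conductances computed from diameter and the intracellular resistivity.

The noise-injection protocol drives the model with the product of a 1D
Gaussian noise movie and a Gaussian bipolar-cell receptive field (σ = 6 grid
units) centred at the injection site (proximal: 25 µm from soma; distal: 85%
of the dendrite length), soft-rectified and affinely calibrated into
[0, 15] nA with mean 6.17 nA and s.d. 1.88 nA. Local dendritic RFs are
estimated from read-out voltages by least squares against the noise movie,
Savitzky–Golay smoothed, and their peak amplitudes normalised to the
injection site, yielding forward/backward propagation profiles and the
channel-density grid search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.signal import savgol_filter

from .errors import InvalidArgumentError

FARADAY = 96485.332          # C/mol
GAS_R = 8.31446              # J/(mol K)

#: passive constants and channel kinetics (Fohlmeister–Miller-type RGC).
DEFAULT_KINETICS = {
    "temperature_c": 32.0,
    "r_a_ohm_cm": 110.0,         # intracellular axial resistivity
    "r_m_ohm_cm2": 15000.0,      # specific membrane resistance (leak = 1/R_m)
    "c_m_uf_cm2": 1.0,
    "v_k_mv": -75.0,
    "v_na_mv": 35.0,
    "v_leak_mv": -65.0,          # chosen so the model rests near -65 mV
    "v_init_mv": -65.0,
    "ca_ext_mm": 1.8,            # external [Ca], for the Nernst potential
    "ca_rest_mm": 1e-4,
    "ca_tau_ms": 20.0,           # first-order Ca extrusion
    "ca_shell_um": 0.1,          # submembrane shell depth for Ca influx
    "kca_diss_mm": 1e-3,         # half-activation of the Ca-activated K current
}

#: reference maximal conductances (S/cm²) in soma and dendrite.
DEFAULT_DENSITIES = {
    "soma":     {"na": 0.08,  "ca": 0.0015, "k": 0.018, "ka": 0.054, "kca": 6.5e-5},
    "dendrite": {"na": 0.025, "ca": 0.002,  "k": 0.012, "ka": 0.036, "kca": 1e-6},
}

#: grid-search axes for the dendritic scaling factors
GRID_S_K = tuple(np.arange(0.0, 2.01, 0.25))
GRID_S_CA = tuple(np.arange(0.0, 2.01, 0.25))
GRID_S_NA = (0.1, 1.0, 2.0)
GRID_S_KCA = (10.0, 100.0, 1000.0, 5000.0, 9000.0)

#: branch-order profiles (order -> (radius µm, segment length µm)). These are
#: plausible synthetic defaults shaped like published EM reconstructions
#: (4ow/4i cells): tapering radius with lengthening segments for the
#: alpha-like cell, near-constant for the mini-like cell. They are package
#: defaults, not measured values.
TOFF_ALPHA_PROFILE = {
    1: (1.30, 12.0), 2: (1.00, 15.0), 3: (0.80, 18.0), 4: (0.65, 24.0),
    5: (0.52, 30.0), 6: (0.43, 38.0), 7: (0.36, 48.0), 8: (0.30, 60.0),
}
TOFF_MINI_PROFILE = {
    1: (0.30, 15.0), 2: (0.28, 15.0), 3: (0.27, 15.0), 4: (0.26, 15.0),
    5: (0.25, 15.0), 6: (0.25, 15.0), 7: (0.25, 15.0), 8: (0.25, 15.0),
}
SOMA_DIAMETER_UM = {"toff-alpha": 20.3, "toff-mini": 13.9}

MAX_COMPARTMENT_UM = 7.0
MAX_DT_MS = 0.05


@dataclass
class ChannelDensities:
    """Reference conductances plus dendritic scaling factors.

    Scaling applies to the dendritic densities only; the A-type K density is
    never scaled."""

    soma: dict = field(default_factory=lambda: dict(DEFAULT_DENSITIES["soma"]))
    dendrite: dict = field(default_factory=lambda: dict(DEFAULT_DENSITIES["dendrite"]))
    s_na: float = 1.0
    s_ca: float = 1.0
    s_k: float = 1.0
    s_kca: float = 1.0

    def scaled_dendrite(self) -> dict:
        d = dict(self.dendrite)
        d["na"] = d["na"] * self.s_na
        d["ca"] = d["ca"] * self.s_ca
        d["k"] = d["k"] * self.s_k
        d["kca"] = d["kca"] * self.s_kca
        if any(v < 0 for v in d.values()):
            raise InvalidArgumentError("negative scaled conductance")
        return d


@dataclass
class CableModel:
    """Discretized ball-and-stick model. Compartment 0 is the soma."""

    diameter_um: np.ndarray      # per compartment
    length_um: np.ndarray
    x_um: np.ndarray             # compartment-centre path distance from soma
    section: np.ndarray          # 0 = soma, then branch order per compartment
    g_dens: np.ndarray           # (n_comp, 6): na, ca, k, ka, kca, leak (S/cm²)
    kinetics: dict

    @property
    def n_comp(self) -> int:
        return len(self.diameter_um)

    @property
    def dendrite_length_um(self) -> float:
        return float(self.length_um[1:].sum())

    def area_cm2(self) -> np.ndarray:
        d = self.diameter_um * 1e-4
        L = self.length_um * 1e-4
        a = np.pi * d * L
        a[0] = np.pi * (self.diameter_um[0] * 1e-4) ** 2   # soma sphere
        return a

    def axial_g_us(self) -> np.ndarray:
        """Axial conductances (µS) between consecutive compartment centres."""
        ra = self.kinetics["r_a_ohm_cm"]
        d_cm = self.diameter_um * 1e-4
        L_cm = self.length_um * 1e-4
        half_r = (L_cm / 2.0) * 4.0 * ra / (np.pi * d_cm ** 2)   # Ω per half-compartment
        r_pair = half_r[:-1] + half_r[1:]
        return 1e6 / r_pair

    def section_centre_compartments(self) -> np.ndarray:
        """Index of the compartment closest to each dendritic section centre."""
        out = []
        for s in np.unique(self.section):
            if s == 0:
                continue
            idx = np.flatnonzero(self.section == s)
            out.append(idx[len(idx) // 2])
        return np.asarray(out, dtype=int)

    def compartment_at(self, x_um: float) -> int:
        """Dendritic compartment whose centre is closest to path distance x."""
        idx = np.arange(1, self.n_comp)
        return int(idx[np.argmin(np.abs(self.x_um[1:] - x_um))])


def build_model(branch_order_profile: dict, channel_densities: ChannelDensities | None = None,
                soma_diameter_um: float = 20.0, kinetics: dict | None = None,
                max_compartment_um: float = MAX_COMPARTMENT_UM) -> CableModel:
    """Assemble the compartmental chain from a branch-order profile.

    Sections are chained in branch-order sequence, each with the profile's
    (median) diameter and segment length, and divided into compartments no
    longer than 7 µm."""
    if not branch_order_profile:
        raise InvalidArgumentError("empty branch-order profile")
    channel_densities = channel_densities or ChannelDensities()
    kin = dict(DEFAULT_KINETICS)
    if kinetics:
        kin.update(kinetics)
    diam = [soma_diameter_um]
    length = [soma_diameter_um]
    sect = [0]
    for order in sorted(branch_order_profile):
        radius, seglen = branch_order_profile[order]
        if seglen <= 0 or radius <= 0:
            raise InvalidArgumentError(f"non-positive geometry at order {order}")
        n = max(1, int(np.ceil(seglen / max_compartment_um)))
        diam.extend([2.0 * radius] * n)
        length.extend([seglen / n] * n)
        sect.extend([order] * n)
    diam = np.asarray(diam, float)
    length = np.asarray(length, float)
    sect = np.asarray(sect, int)
    x = np.concatenate([[0.0], np.cumsum(length[1:]) - length[1:] / 2.0])
    g_leak = 1.0 / kin["r_m_ohm_cm2"]
    dens_soma = channel_densities.soma
    dens_dend = channel_densities.scaled_dendrite()
    g = np.empty((len(diam), 6))
    for i in range(len(diam)):
        src = dens_soma if sect[i] == 0 else dens_dend
        g[i] = [src["na"], src["ca"], src["k"], src["ka"], src["kca"], g_leak]
    return CableModel(diam, length, x, sect, g, kin)


# ---------------------------------------------------------------------------
# Numerical core
# ---------------------------------------------------------------------------

@njit(cache=True)
def _exprel(x):
    # x / (exp(x) - 1), stable near 0
    if abs(x) < 1e-7:
        return 1.0 - x / 2.0
    return x / (math.exp(x) - 1.0)


@njit(cache=True)
def _step_loop(v, m, h, c, n, a, ha, ca_i, g_us, cap_nf, gax_us,
               area_cm2, i_stim, inj_comp, dt, v_k, v_na, v_leak,
               ca_ext, ca_rest, ca_tau, shell_cm, nernst_fac,
               record_every, v_out, ca_out):
    ncomp = v.shape[0]
    nsteps = i_stim.shape[0]
    lower = np.empty(ncomp)
    diag = np.empty(ncomp)
    upper = np.empty(ncomp)
    rhs = np.empty(ncomp)
    cp = np.empty(ncomp)
    dp = np.empty(ncomp)
    rec = 0
    for step in range(nsteps):
        # --- gating (Rush–Larsen at current V) ---
        for i in range(ncomp):
            vi = v[i]
            am = 6.0 * _exprel(-0.1 * (vi + 30.0))
            bm = 20.0 * math.exp(-(vi + 55.0) / 18.0)
            ah = 0.4 * math.exp(-(vi + 50.0) / 20.0)
            bh = 6.0 / (1.0 + math.exp(-0.1 * (vi + 20.0)))
            ac = 3.0 * _exprel(-0.1 * (vi + 13.0))
            bc = 10.0 * math.exp(-(vi + 38.0) / 18.0)
            an = 0.2 * _exprel(-0.1 * (vi + 40.0))
            bn = 0.4 * math.exp(-(vi + 50.0) / 80.0)
            aa = 0.06 * _exprel(-0.1 * (vi + 90.0))
            ba = 0.1 * math.exp(-(vi + 30.0) / 10.0)
            aha = 0.04 * math.exp(-(vi + 70.0) / 20.0)
            bha = 0.6 / (1.0 + math.exp(-0.1 * (vi + 40.0)))
            m[i] = _gate(m[i], am, bm, dt)
            h[i] = _gate(h[i], ah, bh, dt)
            c[i] = _gate(c[i], ac, bc, dt)
            n[i] = _gate(n[i], an, bn, dt)
            a[i] = _gate(a[i], aa, ba, dt)
            ha[i] = _gate(ha[i], aha, bha, dt)
        # --- calcium pool and Nernst potential ---
        for i in range(ncomp):
            v_ca = nernst_fac * math.log(ca_ext / ca_i[i])
            ica_na = g_us[i, 1] * c[i] ** 3 * (v[i] - v_ca)     # nA
            dens = ica_na * 1e-9 / area_cm2[i]                  # A/cm²
            influx = -dens / (2.0 * 96485.332 * shell_cm) * 1e3  # mM/ms
            ca_i[i] += dt * (influx - (ca_i[i] - ca_rest) / ca_tau)
            if ca_i[i] < 1e-8:
                ca_i[i] = 1e-8
        # --- assemble tridiagonal CN system ---
        for i in range(ncomp):
            v_ca = nernst_fac * math.log(ca_ext / ca_i[i])
            g_na = g_us[i, 0] * m[i] ** 3 * h[i]
            g_ca = g_us[i, 1] * c[i] ** 3
            g_k = g_us[i, 2] * n[i] ** 4
            g_ka = g_us[i, 3] * a[i] ** 3 * ha[i]
            caf = ca_i[i] / 1e-3
            g_kca = g_us[i, 4] * (caf * caf) / (1.0 + caf * caf)
            g_l = g_us[i, 5]
            gtot = g_na + g_ca + g_k + g_ka + g_kca + g_l
            src = (g_na * v_na + g_ca * v_ca + (g_k + g_ka + g_kca) * v_k
                   + g_l * v_leak)
            gax = 0.0
            if i > 0:
                gax += gax_us[i - 1]
            if i < ncomp - 1:
                gax += gax_us[i]
            cdt = cap_nf[i] / dt
            diag[i] = cdt + 0.5 * (gtot + gax)
            rhs[i] = (cdt - 0.5 * (gtot + gax)) * v[i] + src
            if i > 0:
                rhs[i] += 0.5 * gax_us[i - 1] * (v[i - 1] + 0.0)
            if i < ncomp - 1:
                rhs[i] += 0.5 * gax_us[i] * (v[i + 1] + 0.0)
        for i in range(ncomp - 1):
            lower[i + 1] = -0.5 * gax_us[i]
            upper[i] = -0.5 * gax_us[i]
        rhs[inj_comp] += i_stim[step]
        # CN: the implicit half couples neighbours; add explicit half above
        # (already in rhs). Thomas algorithm:
        cp[0] = upper[0] / diag[0]
        dp[0] = rhs[0] / diag[0]
        for i in range(1, ncomp):
            denom = diag[i] - lower[i] * cp[i - 1]
            if i < ncomp - 1:
                cp[i] = upper[i] / denom
            dp[i] = (rhs[i] - lower[i] * dp[i - 1]) / denom
        v[ncomp - 1] = dp[ncomp - 1]
        for i in range(ncomp - 2, -1, -1):
            v[i] = dp[i] - cp[i] * v[i + 1]
        if (step + 1) % record_every == 0:
            for i in range(ncomp):
                v_out[rec, i] = v[i]
                ca_out[rec, i] = ca_i[i]
            rec += 1
    return rec


@njit(cache=True)
def _gate(x, alpha, beta, dt):
    s = alpha + beta
    if s <= 0.0:
        return x
    xinf = alpha / s
    return xinf + (x - xinf) * math.exp(-dt * s)


def _steady_gates(v0: float):
    def over(a, b):
        return a / (a + b)
    am = 6.0 * (1.0 - (-0.1 * (v0 + 30.0)) / 2.0) if abs(v0 + 30) < 1e-6 else \
        6.0 * (-0.1 * (v0 + 30.0)) / (np.expm1(-0.1 * (v0 + 30.0)))
    bm = 20.0 * np.exp(-(v0 + 55.0) / 18.0)
    ah = 0.4 * np.exp(-(v0 + 50.0) / 20.0)
    bh = 6.0 / (1.0 + np.exp(-0.1 * (v0 + 20.0)))
    ac = 3.0 * (-0.1 * (v0 + 13.0)) / np.expm1(-0.1 * (v0 + 13.0))
    bc = 10.0 * np.exp(-(v0 + 38.0) / 18.0)
    an = 0.2 * (-0.1 * (v0 + 40.0)) / np.expm1(-0.1 * (v0 + 40.0))
    bn = 0.4 * np.exp(-(v0 + 50.0) / 80.0)
    aa = 0.06 * (-0.1 * (v0 + 90.0)) / np.expm1(-0.1 * (v0 + 90.0))
    ba = 0.1 * np.exp(-(v0 + 30.0) / 10.0)
    aha = 0.04 * np.exp(-(v0 + 70.0) / 20.0)
    bha = 0.6 / (1.0 + np.exp(-0.1 * (v0 + 40.0)))
    return (over(am, bm), over(ah, bh), over(ac, bc), over(an, bn),
            over(aa, ba), over(aha, bha))


def integrate(model: CableModel, i_stim=None, inj_comp: int = 0,
              dt: float = 0.025, duration_ms: float | None = None,
              record_every: int = 1, v_init: float | None = None):
    """Integrate the model; returns dict with times (ms), V (n_rec × n_comp,
    mV) and internal Ca (mM).

    ``i_stim``: per-step injected current (nA) at compartment ``inj_comp``,
    a scalar (constant clamp; requires ``duration_ms``), or None (rest).
    Initial state is the resting steady state at ``v_init``.
    """
    if dt > MAX_DT_MS:
        raise InvalidArgumentError(f"dt must be <= {MAX_DT_MS} ms")
    kin = model.kinetics
    if v_init is None:
        v_init = kin["v_init_mv"]
    if i_stim is None or np.isscalar(i_stim):
        if duration_ms is None:
            raise InvalidArgumentError("duration_ms required without a stimulus array")
        n_steps = int(round(duration_ms / dt))
        i_arr = np.full(n_steps, 0.0 if i_stim is None else float(i_stim))
    else:
        i_arr = np.asarray(i_stim, dtype=float)
        n_steps = len(i_arr)
    area = model.area_cm2()
    g_us = model.g_dens * area[:, None] * 1e6
    cap_nf = kin["c_m_uf_cm2"] * area * 1e3
    gax = model.axial_g_us()
    ncomp = model.n_comp
    v = np.full(ncomp, float(v_init))
    m0, h0, c0, n0, a0, ha0 = _steady_gates(v_init)
    gates = [np.full(ncomp, g) for g in (m0, h0, c0, n0, a0, ha0)]
    ca_i = np.full(ncomp, kin["ca_rest_mm"])
    t_k = 273.15 + kin["temperature_c"]
    nernst_fac = 1e3 * GAS_R * t_k / (2.0 * FARADAY)
    n_rec = n_steps // record_every
    v_out = np.empty((n_rec, ncomp))
    ca_out = np.empty((n_rec, ncomp))
    rec = _step_loop(v, *gates, ca_i, g_us, cap_nf, gax, area, i_arr,
                     int(inj_comp), float(dt), kin["v_k_mv"], kin["v_na_mv"],
                     kin["v_leak_mv"], kin["ca_ext_mm"], kin["ca_rest_mm"],
                     kin["ca_tau_ms"], kin["ca_shell_um"] * 1e-4, nernst_fac,
                     int(record_every), v_out, ca_out)
    if not np.all(np.isfinite(v_out[:rec])):
        raise FloatingPointError(
            "simulation diverged (non-finite voltage); reduce dt or conductances")
    t = (np.arange(1, rec + 1) * record_every) * dt
    for g_arr in gates:
        if np.any(g_arr < -1e-9) or np.any(g_arr > 1 + 1e-9):
            raise FloatingPointError("gating variable left [0, 1]")
    return {"t_ms": t, "v_mv": v_out[:rec], "ca_mm": ca_out[:rec],
            "gates": gates}


# ---------------------------------------------------------------------------
# Noise-injection protocol
# ---------------------------------------------------------------------------

@dataclass
class InjectionProtocol:
    """The dendritic current-injection protocol used for RF read-out."""

    site: str = "proximal"            # 'proximal' (25 µm) | 'distal' (85 %)
    duration_ms: float = 5000.0
    n_space: int = 200                # 1D noise grid
    frame_ms: float = 10.0
    bc_sigma_grid: float = 6.0        # BC RF width, grid units
    i_range_na: tuple = (0.0, 15.0)
    i_mean_na: float = 6.17
    i_sd_na: float = 1.88

    def site_um(self, dendrite_length_um: float) -> float:
        if self.site == "proximal":
            return 25.0
        if self.site == "distal":
            return 0.85 * dendrite_length_um
        raise InvalidArgumentError(f"unknown injection site {self.site!r}")


def _soft_rectify(x: np.ndarray) -> np.ndarray:
    """softplus with unit sharpness: log(1 + exp(x)), overflow-safe."""
    return np.logaddexp(0.0, x)


def make_injection_current(protocol: InjectionProtocol, model: CableModel,
                           seed: int):
    """Build the stimulation current I_stim(t).

    A ``duration × n_space`` Gaussian noise movie is weighted by a Gaussian
    BC receptive field centred at the injection site, summed over space,
    soft-rectified, and affinely scaled so the realized series has exactly
    the target mean and s.d.; the scaling is rejected if the series would
    leave the admissible current range.

    Returns ``(i_stim_frames, noise_movie, inj_comp)``; the current is per
    noise frame (10 ms) and should be expanded sample-and-hold to the
    integration step.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(protocol.duration_ms / protocol.frame_ms))
    noise = rng.standard_normal((n_frames, protocol.n_space))
    L = model.dendrite_length_um
    site_um = protocol.site_um(L)
    pitch = L / protocol.n_space       # grid unit in µm; grid spans the dendrite
    centre = site_um / pitch
    grid = np.arange(protocol.n_space)
    w = np.exp(-0.5 * ((grid - centre) / protocol.bc_sigma_grid) ** 2)
    drive = noise @ w
    drive = drive / drive.std(ddof=0)
    z = _soft_rectify(drive)
    sd = z.std(ddof=0)
    if sd == 0:
        raise InvalidArgumentError("degenerate noise drive")
    # largest scale that realizes the target s.d. while keeping the series
    # inside the admissible range (the mean is pinned exactly); occasional
    # extreme noise draws shrink the s.d. slightly instead of failing
    lo, hi = protocol.i_range_na
    zc = z - z.mean()
    a = protocol.i_sd_na / sd
    if zc.max() > 0:
        a = min(a, (hi - protocol.i_mean_na) / zc.max())
    if zc.min() < 0:
        a = min(a, (protocol.i_mean_na - lo) / (-zc.min()))
    if a <= 0:
        raise InvalidArgumentError("infeasible current calibration")
    i_stim = protocol.i_mean_na + a * zc
    inj_comp = model.compartment_at(site_um)
    return i_stim, noise, inj_comp


def estimate_local_rf(v_frames: np.ndarray, noise: np.ndarray,
                      max_lag: int = 5, savgol_window: int = 31,
                      savgol_order: int = 3, smooth: bool = True):
    """Least-squares 1D spatial RF of a read-out voltage.

    ``v_frames``: voltage averaged per noise frame. For each candidate lag
    the voltage is regressed on the lagged noise movie; the lag with the
    best fit is kept. The weight profile is Savitzky–Golay smoothed
    (window 31, order 3; ``smooth=False`` returns the raw least-squares
    weights) and the peak |amplitude| reported.

    Returns ``(rf, peak_amplitude, best_lag)``.
    """
    v = np.asarray(v_frames, float)
    v = v - v.mean()
    noise = noise - noise.mean(axis=0, keepdims=True)
    nf, ns = noise.shape
    if len(v) != nf:
        raise InvalidArgumentError("voltage frames must match noise frames")
    best = None
    for lag in range(max_lag + 1):
        X = noise[:nf - lag]
        y = v[lag:]
        w, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < ns:
            raise InvalidArgumentError("rank-deficient noise design")
        sse = float(res[0]) if res.size else float(((X @ w - y) ** 2).sum())
        if best is None or sse / max(len(y), 1) < best[0]:
            best = (sse / max(len(y), 1), w, lag)
    _, w, lag = best
    if smooth:
        w = savgol_filter(w, savgol_window, savgol_order)
    return w, float(np.max(np.abs(w))), lag


def propagation_profile(model: CableModel, protocol: InjectionProtocol,
                        seed: int = 0, dt: float = 0.025,
                        readouts: np.ndarray | None = None) -> pd.DataFrame:
    """Normalized local-RF amplitude along the dendrite for one injection.

    RFs are read out at the centre of every dendritic section (or at the
    given compartment indices) and normalized to the amplitude at the
    compartment closest to the injection site (value 1 there).
    """
    i_frames, noise, inj_comp = make_injection_current(protocol, model, seed)
    steps_per_frame = int(round(protocol.frame_ms / dt))
    i_steps = np.repeat(i_frames, steps_per_frame)
    out = integrate(model, i_steps, inj_comp=inj_comp, dt=dt,
                    record_every=steps_per_frame)
    v_frames = out["v_mv"]                      # one row per noise frame
    if readouts is None:
        readouts = model.section_centre_compartments()
    readouts = np.unique(np.concatenate([readouts, [inj_comp]]))
    amps = {}
    for comp in readouts:
        _, amp, _ = estimate_local_rf(v_frames[:, comp], noise)
        amps[int(comp)] = amp
    ref = amps[int(inj_comp)]
    if ref == 0:
        raise InvalidArgumentError("zero amplitude at the injection site")
    rows = [{"compartment": comp, "x_um": float(model.x_um[comp]),
             "amplitude": amp, "normalized": amp / ref,
             "is_injection_site": comp == inj_comp}
            for comp, amp in sorted(amps.items())]
    return pd.DataFrame(rows)


# White-box channel combinations: dendritic scaling factors selected from
# the grid search as consistent with the experimentally derived hypotheses
# (forward-dominant transfer in the alpha-like model; backward transfer in
# the mini-like model exceeding the alpha model's, at higher K / much lower
# Na than the alpha combination).
WHITEBOX_ALPHA = dict(s_na=2.0, s_ca=2.0, s_k=1.0, s_kca=10.0)
WHITEBOX_MINI = dict(s_na=0.1, s_ca=1.0, s_k=1.25, s_kca=10.0)


def model_for(family: str, scales: dict | None = None) -> CableModel:
    """Convenience constructor for the two study morphologies."""
    profile = {"toff-alpha": TOFF_ALPHA_PROFILE,
               "toff-mini": TOFF_MINI_PROFILE}[family]
    dens = ChannelDensities(**(scales or {}))
    return build_model(profile, dens, soma_diameter_um=SOMA_DIAMETER_UM[family])


def forward_backward(model: CableModel, seed: int = 0, dt: float = 0.025
                     ) -> dict:
    """Forward and backward propagation ratios of one model.

    forward: distal injection, read out at the most proximal dendritic
    compartment; backward: proximal injection, read out at the most distal
    compartment. Both are local-RF peak amplitudes normalized to the
    respective injection site."""
    prox_comp = 1
    dist_comp = model.n_comp - 1
    out = {}
    for site, target in (("proximal", dist_comp), ("distal", prox_comp)):
        prof = propagation_profile(model, InjectionProtocol(site=site),
                                   seed=seed, dt=dt,
                                   readouts=np.array([prox_comp, dist_comp]))
        ratio = float(prof.loc[prof.compartment == target, "normalized"].iloc[0])
        out["backward" if site == "proximal" else "forward"] = ratio
    return out


def grid_search(family: str, combos=None, seed: int = 0,
                dt: float = 0.025) -> pd.DataFrame:
    """Forward/backward ratios over channel-density combinations.

    ``combos``: iterable of dicts with keys s_na, s_ca, s_k, s_kca (default:
    the full factorial grid; pass a subset for scaled-down runs). Failing
    simulations are recorded as NaN and the scan continues."""
    if combos is None:
        combos = [dict(s_na=sna, s_ca=sca, s_k=sk, s_kca=skca)
                  for sna in GRID_S_NA for sca in GRID_S_CA
                  for sk in GRID_S_K for skca in GRID_S_KCA]
    rows = []
    for combo in combos:
        row = dict(combo)
        try:
            model = model_for(family, combo)
            row.update(forward_backward(model, seed=seed, dt=dt))
        except (InvalidArgumentError, FloatingPointError):
            row.update(forward=np.nan, backward=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
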