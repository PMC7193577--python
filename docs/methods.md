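# Methods

`dendrint` analyses dendritic integration in single retinal ganglion cells
(RGCs) recorded with two-photon Ca²⁺ imaging, and ships a synthetic-data
generator that emulates the recording conditions with known ground truth.
This note documents the models, the numerical choices, and what passing
tests do and do not establish.

## Synthetic recordings

**Dense noise.** The RF-mapping stimulus is a 20 × 15 binary checkerboard
(30 µm pixels) refreshed at 5 Hz. Each pixel shows a *balanced* sequence:
an equal multiset of 0s and 1s (odd lengths carry a surplus of one, its
value randomized) shuffled by a seeded permutation, so |#1 − #0| ≤ 1 per
pixel by construction. Identical seeds give bit-identical movies.

**Chirp.** One luminance trace in [0, 1] around a 0.5 background: a 3-s
bright step (onset at 6 s — the lead-in provides the 5-s baseline the
preprocessing requires), an accelerating 0.5→8 Hz sinusoid (linear
frequency ramp), and a 2 Hz sinusoid with linearly ramping contrast, in
that order. The local variant is the same waveform with 100 µm aperture
metadata (versus 800 × 600 µm full field).

**Planted RFs and Ca²⁺ movies.** Each planted ROI carries a separable
Gaussian spatio-temporal RF. The linear drive is the RF-projected,
zero-mean stimulus convolved with a biphasic temporal kernel at the
stimulus refresh; the fluorescence trace integrates that drive through a
mono-exponential indicator, dCa/dt = drive − Ca/τ with τ = 200 ms
(configurable). Movies are rendered at 31.25 Hz on a 64 × 16 px field:
ROI discs carry their (unit-s.d.) noiseless trace, every pixel receives
i.i.d. Gaussian noise of s.d. σ, so the movie SNR is 1/σ (tests use
σ = 0.2, i.e. SNR 5). Two integration profiles are provided: *local*
(RF centred on the ROI, size shrinking with dendritic distance,
tOff-alpha-like) and *global* (all RFs at the arbour centre of mass,
tOff-mini-like). Note the consequence of the indicator leak: the trace
gradient is the drive *minus* Ca/τ, i.e. a high-passed version of the
drive. The spatial RF is unaffected (separability), but the gradient's
raw correlation with the drive is ≈ 0.76 at these time constants; tests
assert the exact generative identity instead.

**Morphological cohorts.** Per-type parameter specifications list the mean
and "±" dispersion of the four clustering parameters (n = 17/5/4/5 cells
for tOff alpha / tOff mini / sOff / F-miniOff). The package treats the ±
values as the per-cell s.d. (draws truncated at 2 dispersions), which
keeps the four types well separated — the regime all recovery tests
assume; a `pm_is_sem=True` switch converts them as s.e.m. × √n instead,
giving a much broader, overlapping spread under which perfect 4-type
recovery holds for only ≈ 55% of cohorts. That overlap is a property of
1D 2-means on nearby clusters, not of the implementation.

**Parametric skeletons.** A planar tree is grown by nearest-neighbour
attachment of tips filling a disc; the disc radius and centre offset are
calibrated in a short fixed-point loop against the *measured* hull area
and centroid offset, and two-stratum depths (central 0.625 / marginal
0.875 on the IPL axis) are assigned along the DFS edge order with the
central/marginal boundary found by bisection against the measured arbour
density difference. Realized parameters track their targets to ≈ 3%
(ADD to < 0.1 a.u.). Radii are 0.5 µm with a soma sphere matching the
target soma area. Unreachable targets (asymmetry ≳ 2× the arbour radius)
raise a generation failure after a bounded number of fresh attempts.

**Current-injection experiments.** 500-ms somatic steps (≤ 0.5 nA, 12-s
spacing) produce spike counts via rate = gain·(I − rheobase)⁺ (Poisson
jitter optional; deterministic rounding by default so noiseless
regressions are exact). Each dendritic ROI's Ca²⁺ trace carries one flat
pulse per step whose *trapezoidal integral equals slope(distance) × spike
count* in baseline-s.d. units; with noise enabled the signal is pre-scaled
by the noise s.d. so the downstream baseline normalization returns AUCs on
the planted scale. Default slopes (3.03/1.40 proximal/distal for the
strong-backpropagation profile, 0.44/0.24 for the weak one) set the
generator's contrast between profiles.

## Analysis pipeline

**ROI extraction.** s.d. image over time (population s.d. everywhere, for
bit-reproducibility) → dendritic pixels above mean + 1 s.d. → ρ_threshold
as the mean pairwise Pearson correlation of the 100 most responsive
dendritic pixels (all of them if fewer) → greedy seeded growth: seeds in
descending s.d. order, regions absorb unassigned dendritic pixels within
3 µm of any member whose trace correlates with the *seed* trace above
ρ_threshold, iterated to stability. The procedure is deterministic; masks
are disjoint; raising ρ_threshold can only shrink regions. Correlations
use raw traces by default (an optional 0.1 Hz high-pass is available).

**RF estimation (ASD).** The response is the temporal gradient of the
Ca²⁺ trace (central differences); the design matrix holds the
sample-and-hold stimulus at lags covering −1000…0 ms (lag count =
⌈window × response rate⌉, e.g. 32 at 31.25 Hz). The STRF prior is a
Kronecker product of squared-exponential kernels over the 2D pixel grid
and the lag axis, C = e^(−ρ) K_s(δ_s) ⊗ K_t(δ_t), with a shared scale —
this keeps every evidence evaluation a p × p dense solve (p = pixels ×
lags) instead of an intractable joint kernel. Evidence is computed in
weight space via the determinant lemma and Woodbury identity from the
precomputed sufficient statistics XᵀX and Xᵀy; hyperparameters
(ρ, log δ_s, log δ_t, log δ²) are optimized by Nelder–Mead (default
200 iterations, 1e-5 relative tolerance; kernels carry a 1e-6 diagonal
jitter; non-positive-definite proposals are rejected). The scale and
noise variance are parametrized relative to var(y), which makes the whole
fit *exactly* equivariant under rescaling of the response. In the
zero-smoothness limit the MAP estimate equals ridge regression with
penalty δ²e^ρ (tested to 1e-6). Recovery benchmarks build the design at
the stimulus refresh (5 lags over 1 s, 1500 design rows for a 5-min
stimulus) with the gradient bin-averaged per stimulus frame — the
problem size that keeps a 10-seed benchmark within minutes while leaving
the estimator itself rate-agnostic.

**Spatial map, contours, quality.** The spatial RF is the first left
singular vector of the (space × lag) STRF, signed so its extremum is
positive (the temporal component absorbs the sign, leaving the product
unchanged). Maps are upsampled ×10 by bicubic interpolation on a grid
with pitch exactly 1/10 pixel (endpoints on the original pixel centres —
`ndimage.zoom`'s default grid would distort the pitch by (N−1)/(10N−1)
and bias contour areas by ~10%), min–max normalized, and contoured by
marching squares at {0.60, 0.65, 0.70}; contours touching the border are
discarded as unclosed. The irregularity index is Ii = 1 −
A_contour/A_convex-hull of the contour polygon. A receptive field passes
the quality gate iff the 0.60 level set is a single closed contour with
Ii < 0.1 and area > 1800 µm².

**RF metrics.** Offset distance (ROI centre to contour centroid), offset
angle (0° = shifted exactly toward the arbour's length-weighted centre of
mass), and overlap index Oi = A_overlap/min(A₁, A₂) via exact polygon
clipping. Overlap maps hex-bin (Oi, dendritic distance, angular distance)
triples on the two-interleaved-lattice construction (25 µm × 15° pitch;
bins with < 3 pairs masked); bin counts always sum to the pair count.

**Morphology.** Arbour density difference is the normalized central-minus-
marginal cable length, (L_c − L_m)/L_total, with edges split analytically
at the ChAT-band depths (0.48/0.77) and an a.u. scale factor (default 10)
so reference-type targets are representable; it is bounded in ±scale by
construction. Area is the convex hull of the z-projected arbour with
edges resampled at 1 µm (soma included); asymmetry is the planar distance
from the length-weighted cable centroid to the soma; soma size is πr²
from the SWC sphere or a mask area. ROI centres snap to the nearest point
on the nearest edge (unmatched beyond 10 µm); dendritic distance is the
tree path length between snapped points; angular distance is the planar
angle at the last common branching node (walking toward the soma, which
counts as a branching node). Clustering is the fixed three-step decision
tree — ADD split, then soma size within the low-ADD group (large = tOff
alpha), then asymmetry within the high-ADD group (high = F-miniOff) —
each split a deterministic 1D 2-means initialized at the extreme values
(scikit-learn KMeans, single init; all-identical values warn and fall to
the lower cluster). One-dimensional 2-means is equivariant under positive
affine rescaling, so the labels are scale-free.

**Temporal metrics.** Chirp trials are linearly upsampled to 500 Hz,
baseline-subtracted and normalized by the baseline s.d. (2500 samples
before stimulus onset; zero-variance baselines skip the division).
Qi = Var_t[⟨C⟩_r] / ⟨Var_t[C]⟩_r — note the denominator is the trial
average of per-trial time variance, the only reading consistent with the
analytic limits Qi = 1 (identical trials) and Qi ≈ 1/R (independent
noise). Window detection smooths the mean trace with the exact
3000-fold [1,2,1]/4 composite kernel (one convolution; identical to
iterating by associativity; ≈ Gaussian with σ = √1500 ≈ 38.7 samples;
reflect boundaries; kernel truncated at 7σ, error < 1e-10) and thresholds
|trace − baseline mean| at 2 baseline s.d.; crossings must persist 0.5 s,
because smoothed-noise excursions above 2 s.d. occur constantly and last
up to ≈ 0.4 s (measured over 30 noise seeds) — a crossing-based edge also
sits ≈ 3 smoothing widths outside the true edge when the response dwarfs
the baseline noise, which bounds the achievable onset accuracy.
Ti = 1 − (T_off − T_on)/T_stimulus (clipped at 0 with a warning);
POi = (Σ_on − Σ_off)/(Σ_on + Σ_off) over 3-s windows after stimulus onset
and offset, computed on the smoothed trace zeroed outside the detected
response window (consistent with the detection; onset-only responses give
exactly +1, offset-only exactly −1). Backpropagation analysis: Ca traces
normalized by the s.d. of their first 5 s, 5-s pre-step mean subtracted,
trapezoidal AUC and somatic spike count (upward −10 mV crossings) in a
1.6-s window from step onset; per-group OLS slopes with 95% CIs, an
F-test of the spike × group interaction, and Tukey-adjusted pairwise
slope contrasts from the full-interaction model via the studentized-range
distribution.

## Biophysical model

Ball-and-stick: a spherical soma plus a chain of cylindrical sections,
one per branch order, from a branch-order profile (median radius, median
segment length). The shipped profiles are plausible synthetic defaults
shaped like EM reconstructions — tapering radius with lengthening
segments for the alpha-like cell (total 245 µm), near-constant 0.25-µm
radius and 15-µm segments for the mini-like cell (120 µm) — not measured
values. Compartments are ≤ 7 µm; passive constants R_a = 110 Ω·cm,
R_m = 15 kΩ·cm², C_m = 1 µF/cm²; V_K = −75 mV, V_Na = +35 mV; V_Ca from
the Nernst relation with 1.8 mM external Ca at 32 °C. Channel gating
(Na m³h, Ca c³, delayed-rectifier K n⁴, A-type K a³h_A, Ca-activated K
with Ca²/(Ca² + K_d²) activation, K_d = 1 µM, and leak with
V_leak = −65 mV chosen so the model rests near −65 mV) follows the
classical Fohlmeister–Miller RGC formulation; all rate constants and the
Ca pool (0.1 µm shell, 20 ms extrusion, 0.1 µM rest) live in a plain-dict
config so every constant is pinned and serialisable. Integration is
Crank–Nicolson on the tridiagonal voltage system (Thomas algorithm,
numba-compiled) with Rush–Larsen exponential gating updates; dt ≤ 0.05 ms
is enforced, gating stays in [0, 1], and the passive steady state matches
the sealed-end cable solution to numerical precision.

**Noise-injection protocol.** A 5000 ms × 200-sample 1D Gaussian noise
movie (10-ms frames; the grid spans the dendrite, so one grid unit is
L/200 µm) is weighted by a Gaussian bipolar-cell RF (σ = 6 grid units)
centred at the injection site (proximal: 25 µm from soma; distal: 85% of
dendrite length), summed over space, soft-rectified (softplus, unit
sharpness) and affinely calibrated to mean 6.17 nA and s.d. 1.88 nA: the
mean is pinned exactly and the scale is the largest value realizing the
target s.d. while keeping the series inside [0, 15] nA, so rare extreme
draws shrink the s.d. slightly instead of failing. Local dendritic RFs
are estimated per read-out compartment by least squares of the
frame-resolution voltage on the (demeaned) noise movie at the best single
lag (0–5 frames), Savitzky–Golay smoothed (window 31, order 3); peak
amplitudes are normalized to the injection-site compartment. Forward
transfer = distal injection, most-proximal read-out; backward = proximal
injection, most-distal read-out.

**Grid search and white boxes.** Dendritic densities scale by factors
s_K, s_Ca ∈ {0…2, step 0.25}, s_Na ∈ {0.1, 1, 2}, s_KCa ∈ {10, 100,
1000, 5000, 9000} (A-type K never scaled; somatic densities fixed). The
shipped white-box combinations were selected from this grid as consistent
with the experimentally derived hypotheses: at (s_Na=2, s_Ca=2, s_K=1,
s_KCa=10) the alpha morphology is forward-dominant while the identical
densities nearly extinguish forward transfer on the mini morphology; at
(s_Na=0.1, s_Ca=1, s_K=1.25, s_KCa=10) — higher K, lower Na — the mini
model's backward transfer exceeds both its own forward transfer and the
alpha model's backward transfer. A caveat: with the prescribed point
injection (mean 6.17 nA into sub-µm cable) the membrane near the
injection site is strongly depolarized, Na is largely inactivated there,
and backward transfer *decreases* monotonically with dendritic K in this
implementation; the "higher-K" character of the mini white box therefore
holds as the comparative statement above, not as a K-dose effect.

## What the synthetic tests do not show

The generator plants disjoint, internally coherent ROIs with independent
signals, Gaussian RFs, linear encoding and i.i.d. pixel noise. Real
recordings add motion, neuropil contamination, overlapping sources,
nonlinear encoding, correlated noise and indicator saturation; passing
recovery tests therefore validates the implementation against its stated
model, not performance on arbitrary real data. Morphology recovery is
demonstrated in the well-separated (±-as-s.d.) regime; the biophysical
white boxes are statements about this ball-and-stick model under the
stated drive, not measurements of real channel densities.

## Problem sizes used by the test suite

RF recovery: 20 × 15 grid, 1500 stimulus frames, 5 lags, SNR 5, 10 seeds
(simplex capped at 40 iterations). ROI recovery: 60-s movies, 10 seeds.
Clustering: 20 cohorts of 31 cells. Cable checks: 3-section passive cable
and the three white-box simulations (5-s drives at dt = 0.025 ms). These
sizes are the package's benchmark defaults; all are configurable.
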