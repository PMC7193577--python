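# dendrint

Analysis of **dendritic integration in single retinal ganglion cells
(RGCs)** from two-photon Ca²⁺ imaging, with a fully synthetic test bed.
The package is aimed at systems-neuroscience labs that record local
dendritic activity under visual stimulation and want a tested, scriptable
pipeline from raw image stacks to receptive-field (RF) and
signal-propagation statistics.

It covers, end to end:

- **Synthetic data** with known ground truth: balanced binary dense-noise
  and chirp stimuli, parametric RGC skeletons realizing target
  morphological parameters, rendered dendritic Ca²⁺ movies with planted
  Gaussian RFs, chirp trial sets with controllable SNR, and somatic
  current-injection experiments.
- **ROI extraction** from time-lapsed stacks by pixel correlation: s.d.
  image → dendritic pixels (mean + 1 s.d.) → correlation threshold ρ from
  the 100 most responsive pixels → seeded region growth (3 µm, ρ > ρ_thr).
- **RF estimation** with Automatic Smoothness Determination (ASD): the
  trace gradient y is modelled as y = kᵀX + ε with a smoothness prior
  C_ij = exp(−ρ − Δ_ij/2δ) on the spatio-temporal filter k, hyperparameters
  set by evidence maximization and k by MAP regression; then SVD spatial
  maps, marching-squares contours at {0.60, 0.65, 0.70}, the irregularity
  index Ii = 1 − A_contour/A_hull, and the quality gate (single contour,
  Ii < 0.1, A > 1800 µm²).
- **RF geometry metrics**: offset distance and angle, overlap index
  Oi = A_overlap/min(A₁, A₂), hex-binned overlap maps over dendritic and
  angular distance.
- **Temporal metrics**: quality index Qi = Var_t[⟨C⟩_r]/⟨Var_t[C]⟩_r,
  pairwise trace correlation, binomially smoothed response-window
  detection, transience Ti and polarity POi, and the current-injection
  backpropagation regression (Ca²⁺ AUC vs somatic spike count, with slope
  contrasts between groups).
- **Morphology**: SWC skeleton model, the four type-separating parameters
  (arbour density difference, hull area, asymmetry, soma size), dendritic
  and angular distance between calibrated ROIs, and the fixed three-step
  1D k-means tree assigning {tOff alpha, tOff mini, sOff, F-miniOff}.
- **Biophysics**: a ball-and-stick compartmental model (cable equation,
  Crank–Nicolson) with Fohlmeister–Miller-type channels, the calibrated
  noise-injection protocol (mean 6.17 nA, s.d. 1.88 nA in [0, 15] nA),
  local-RF read-outs along the dendrite, and the channel-density grid
  search for forward/backward propagation regimes.

## Worked example

Generate a tOff-alpha-like recording, extract ROIs, and estimate one
dendritic RF:

```python
import numpy as np
from dendrint import synthetic_data as S, roi_extraction as R
from dendrint import rf_estimation as RF, morphology as M

skel = S.gen_skeleton(S.OFF_TYPE_SPECS["tOff alpha"], seed=1)
print({k: round(v, 1) for k, v in vars(M.morpho_params(skel)).items()})
# {'arbour_density_difference': -2.3, 'area': 55089.7,
#  'asymmetry': 47.3, 'soma_size': 311.7}

stim = S.gen_dense_noise(duration=300.0, seed=1)          # 1500 frames, 5 Hz
rec = S.gen_ca_movie(stim, skel, rf_family="local", noise_sigma=0.2, seed=1)
rois, rho = R.extract_rois(rec.stack)
print(f"rho_threshold={rho:.3f}, n_rois={len(rois)}")
# rho_threshold=0.293, n_rois=5

roi = rois[0]
grad = RF.response_gradient(roi.trace, rec.stack.frame_rate)
t = np.arange(len(grad)) / rec.stack.frame_rate
idx = np.floor(t * stim.refresh_rate).astype(int)
y = np.bincount(idx, weights=grad) / np.bincount(idx)     # per-frame gradient
X, kept = RF.build_design(stim, stim.frame_times())
model = RF.asd_fit(X, y[kept], (15, 20), n_lags=5, max_iter=40)
sp = RF.svd_spatial_map(model.strf)
report = RF.rf_quality_filter(RF.extract_contours(sp)[0.60])
print(report.passed, round(report.area), round(report.irregularity, 3))
# True 5004 0.0
```

The generated cell's parameters land on the tOff-alpha row of the type
table (ADD −2.3 a.u., 55.1 × 10³ µm² arbour, 312 µm² soma); all five
planted ROIs are recovered; the fitted RF passes the quality gate with a
5004 µm² contour of irregularity 0.0, and its spatial map correlates with
the planted Gaussian at r = 0.98.

A thin CLI wraps the same functions (`dendrint simulate | rois | fit-rf |
rf-metrics | temporal | backprop | morph | cluster | cable | grid-search |
run`); `dendrint run --seed 0 --out out/` executes the synthetic pipeline
end to end.

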