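import numpy as np
import pytest

from dendrint import synthetic_data as S
from dendrint import temporal_metrics as T
from dendrint.errors import InvalidArgumentError, UndefinedMetricError


def traceset(trials, rate=500.0, on=6.0, off=9.0):
    return T.TraceSet(np.asarray(trials, float), rate, on, off)


def step_trace(rate=500.0, total=20.0, segments=()):
    """Zeros with (start, stop, height) bumps."""
    t = np.arange(int(total * rate)) / rate
    x = np.zeros_like(t)
    for a, b, h in segments:
        x[(t >= a) & (t < b)] = h
    return x


class TestQualityIndex:
    def test_identical_trials_give_one(self):
        base = np.sin(np.linspace(0, 20, 4000))
        ts = traceset(np.tile(base[:, None], (1, 5)))
        assert T.quality_index(ts) == pytest.approx(1.0)

    def test_pure_noise_scales_as_one_over_r(self):
        rng = np.random.default_rng(0)
        R = 10
        qis = [T.quality_index(traceset(rng.normal(size=(500, R))))
               for _ in range(100)]
        assert np.mean(qis) == pytest.approx(1.0 / R, abs=0.03)

    def test_single_repetition_rejected(self):
        with pytest.raises(InvalidArgumentError):
            T.quality_index(traceset(np.zeros((100, 1))))

    def test_monotone_in_snr(self):
        chirp = S.gen_chirp()
        qis = [T.quality_index(S.gen_chirp_traceset(chirp, 5, snr, seed=1))
               for snr in (0.5, 2.0, 8.0)]
        assert qis[0] < qis[1] < qis[2]


class TestPairwiseCorrelation:
    def test_identity_and_negation(self):
        x = np.sin(np.linspace(0, 5, 300))
        assert T.pairwise_correlation(x, x) == pytest.approx(1.0)
        assert T.pairwise_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 400))
        za, zb = a - a.mean(), b - b.mean()
        oracle = (za @ zb) / np.sqrt((za @ za) * (zb @ zb))
        assert T.pairwise_correlation(a, b) == pytest.approx(oracle)


class TestBinomialSmoothing:
    def test_composite_kernel_equals_literal_iteration(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        for n in (1, 7, 40):
            assert np.allclose(T.binomial_smooth(x, n),
                               T.binomial_smooth(x, n, literal=True),
                               atol=1e-10)

    def test_preserves_constant(self):
        assert np.allclose(T.binomial_smooth(np.full(5000, 3.3)), 3.3)


class TestResponseWindow:
    def test_boxcar_onset_offset(self):
        rng = np.random.default_rng(30)
        x = step_trace(segments=[(6.0, 9.0, 5.0)]) + rng.normal(0, 0.05, 10000)
        win = T.response_window(x, 500.0, 6.0, 9.0)
        assert win.responsive
        # smoothing blurs edges by ~sigma = sqrt(3000/2)/500 s = 0.077 s
        assert win.onset == pytest.approx(6.0, abs=0.3)
        assert win.offset == pytest.approx(9.0, abs=0.3)

    def test_flat_trace_nonresponsive(self):
        x = np.zeros(10000)
        win = T.response_window(x, 500.0, 6.0, 9.0)
        assert not win.responsive

    def test_transient_width_within_kernel_scale(self):
        # a threshold at 2 s.d. of the baseline crosses the Gaussian-blurred
        # edge of a strong bump at z = Phi^-1(1 - thr/height) ~ 3 smoothing
        # widths outside the true edge, so 4 sigma bounds the detection error
        rng = np.random.default_rng(31)
        x = step_trace(segments=[(6.2, 7.2, 4.0)]) + rng.normal(0, 0.05, 10000)
        win = T.response_window(x, 500.0, 6.0, 9.0)
        sigma_s = np.sqrt(3000 / 2.0) / 500.0
        assert abs(win.onset - 6.2) < 4 * sigma_s
        assert abs(win.offset - 7.2) < 4 * sigma_s


class TestTransienceIndex:
    def test_full_span_zero(self):
        win = T.ResponseWindow(6.0, 9.0, 6.0, 9.0)
        assert T.transience_index(win) == pytest.approx(0.0)

    def test_half_span(self):
        win = T.ResponseWindow(6.0, 7.5, 6.0, 9.0)
        assert T.transience_index(win) == pytest.approx(0.5)

    def test_overlong_clipped_with_warning(self):
        win = T.ResponseWindow(6.0, 12.5, 6.0, 9.0)
        with pytest.warns(UserWarning):
            assert T.transience_index(win) == 0.0


class TestPolarityIndex:
    # analytic cases: the response window is known exactly by construction

    def test_onset_only_plus_one(self):
        x = step_trace(segments=[(6.1, 7.0, 3.0)])
        win = T.ResponseWindow(6.1, 7.0, 6.0, 9.0)
        assert T.polarity_index(x, win, 500.0) == pytest.approx(1.0)

    def test_offset_only_minus_one(self):
        x = step_trace(segments=[(9.1, 10.0, 3.0)])
        win = T.ResponseWindow(9.1, 10.0, 6.0, 9.0)
        assert T.polarity_index(x, win, 500.0) == pytest.approx(-1.0)

    def test_balanced_zero(self):
        # bumps exactly 3 s apart (the window shift), with all smoothing
        # leaks clear of the stimulus-window and response-window boundaries
        x = step_trace(segments=[(6.9, 7.7, 3.0), (9.9, 10.7, 3.0)])
        win = T.ResponseWindow(6.2, 11.4, 6.0, 9.0)
        assert T.polarity_index(x, win, 500.0) == pytest.approx(0.0, abs=1e-9)

    def test_antisymmetric_under_segment_swap(self):
        a = step_trace(segments=[(6.9, 7.7, 3.0), (9.9, 10.7, 1.0)])
        b = step_trace(segments=[(6.9, 7.7, 1.0), (9.9, 10.7, 3.0)])
        win = T.ResponseWindow(6.2, 11.4, 6.0, 9.0)
        pa = T.polarity_index(a, win, 500.0)
        pb = T.polarity_index(b, win, 500.0)
        assert pa == pytest.approx(-pb, abs=1e-9)
        assert -1.0 <= pa <= 1.0


class TestPreprocessChirp:
    def test_baseline_standardized(self):
        chirp = S.gen_chirp()
        raw = S.gen_chirp_traceset(chirp, n_reps=4, snr=3.0, seed=4)
        ts = T.preprocess_chirp(raw)
        assert ts.sample_rate == 500.0
        on = int(ts.stimulus_onset * 500)
        base = ts.trials[on - 2500:on]
        assert np.allclose(base.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(base.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_ramp_resampled_exactly(self):
        t = np.arange(0, 2000) / 100.0
        raw = T.TraceSet(t[:, None] * 2.0, 100.0, 6.0, 9.0)
        ts = T.preprocess_chirp(raw)
        # linear ramp stays linear under linear interpolation
        d = np.diff(ts.trials[:, 0])
        assert np.allclose(d, d[0], atol=1e-9)

    def test_insufficient_baseline_rejected(self):
        raw = T.TraceSet(np.zeros((500, 2)), 100.0, 1.0, 2.0)
        with pytest.raises(InvalidArgumentError):
            T.preprocess_chirp(raw)


class TestSpikeCount:
    def test_flat_trace_zero(self):
        assert T.spike_count(np.full(1000, -65.0)) == 0

    def test_planted_spikes_counted(self):
        v = np.full(20000, -65.0)
        for k in range(7):
            v[1000 + 2000 * k: 1020 + 2000 * k] = 20.0
        assert T.spike_count(v) == 7

    def test_threshold_above_peaks(self):
        v = np.full(1000, -65.0)
        v[100:110] = -20.0
        assert T.spike_count(v, threshold=-10.0) == 0
        assert T.spike_count(v, threshold=-30.0) == 1


class TestBackpropRegression:
    def _experiment(self, profile, seed=0):
        steps = np.arange(0.1, 0.51, 0.1)
        v, ca, onsets, counts = S.gen_current_injection(profile, steps, seed=seed)
        return T.BackpropExperiment(
            voltage=v, v_sample_rate=1e4,
            ca_traces={profile.name: ca},
            step_onsets=onsets, step_amplitudes=steps), counts

    def test_noiseless_slope_recovered_exactly(self):
        prof = S.BackpropCellProfile("p", slope_proximal=3.03,
                                     slope_distal=3.03, noise_sd=0.0)
        exp, counts = self._experiment(prof)
        res = T.backprop_regression(exp)
        assert res.groups.loc["p", "slope"] == pytest.approx(3.03, rel=1e-6)
        assert res.groups.loc["p", "r2"] == pytest.approx(1.0)

    def test_zero_slope_ci_contains_zero(self):
        prof = S.BackpropCellProfile("z", slope_proximal=0.0, slope_distal=0.0,
                                     noise_sd=1.0)
        exp, _ = self._experiment(prof, seed=3)
        res = T.backprop_regression(exp)
        lo, hi = res.groups.loc["z", ["ci_low", "ci_high"]]
        assert lo <= 0.0 <= hi

    def test_interaction_detects_slope_difference(self):
        """Two groups with slopes 3.0 vs 0.4: the interaction F-test should
        reject equality of slopes in essentially every replicate."""
        rejections = 0
        n_rep = 10
        for seed in range(n_rep):
            steps = np.tile(np.arange(0.1, 0.51, 0.1), 2)
            strong = S.BackpropCellProfile("strong", slope_proximal=3.0,
                                           slope_distal=3.0, noise_sd=1.0)
            weak = S.BackpropCellProfile("weak", slope_proximal=0.4,
                                         slope_distal=0.4, noise_sd=1.0)
            v1, ca1, on1, _ = S.gen_current_injection(
                strong, steps, seed=seed, n_rois_per_distance=5)
            v2, ca2, on2, _ = S.gen_current_injection(
                weak, steps, seed=seed + 100, n_rois_per_distance=5)
            exp = T.BackpropExperiment(
                voltage=v1, v_sample_rate=1e4,
                ca_traces={"strong": ca1, "weak": ca2},
                step_onsets=on1, step_amplitudes=steps)
            res = T.backprop_regression(exp)
            rejections += res.interaction_p < 0.05
            assert len(res.pairwise) == 1
        assert rejections == n_rep

    def test_spike_counts_increase_with_amplitude(self):
        prof = S.STRONG_BACKPROP
        steps = np.arange(0.1, 0.51, 0.1)
        _, _, _, counts = S.gen_current_injection(prof, steps, seed=1)
        assert np.all(np.diff(counts) >= 0)
        assert counts[-1] > counts[0]

    def test_zero_current_zero_spikes(self):
        prof = S.STRONG_BACKPROP
        v, ca, onsets, counts = S.gen_current_injection(prof, [0.0], seed=2)
        assert counts[0] == 0
        assert np.all(v <= -60.0)


class TestQiGateRobustness:
    def test_type_ordering_stable_under_stricter_gate(self):
        """Mean pairwise correlation ordering across synthetic 'types' is the
        same for Qi > 0.4 and Qi > 0.5 gates."""
        chirp = S.gen_chirp()
        rng_types = {"hi-corr": (0.9, 8.0), "mid-corr": (0.55, 4.0),
                     "lo-corr": (0.25, 2.5)}
        order = {}
        for gate in (0.4, 0.5):
            means = {}
            for name, (corr, snr) in rng_types.items():
                rng = np.random.default_rng(42)
                base = S.chirp_mean_response(chirp)
                rois = []
                for i in range(12):
                    indiv = corr * base + (1 - corr) * np.roll(base, 37 * (i + 1))
                    ts = S.gen_chirp_traceset(chirp, 5, snr, seed=i,
                                              mean_response=indiv)
                    ts = T.preprocess_chirp(ts)
                    if T.quality_index(ts) > gate:
                        rois.append(ts.mean_trace())
                cc = [T.pairwise_correlation(rois[i], rois[j])
                      for i in range(len(rois)) for j in range(i + 1, len(rois))]
                means[name] = np.mean(cc)
            order[gate] = sorted(means, key=means.get)
        assert order[0.4] == order[0.5]
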