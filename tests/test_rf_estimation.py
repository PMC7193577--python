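import numpy as np
import pytest

from dendrint import rf_estimation as RF
from dendrint import synthetic_data as S
from dendrint.errors import InvalidArgumentError


class TestResponseGradient:
    def test_linear_ramp(self):
        t = np.arange(100)
        y = RF.response_gradient(0.2 * t, frame_rate=31.25)
        assert np.allclose(y, 0.2 * 31.25)

    def test_constant_trace(self):
        assert np.allclose(RF.response_gradient(np.full(50, 3.0), 10.0), 0.0)

    def test_gradient_linear_in_planted_drive(self, noise_stimulus):
        """The noiseless Ca trace obeys dCa/dt = drive - Ca/τ, so the
        gradient plus the known leak term reconstructs the planted drive
        almost perfectly; the raw gradient alone is a high-passed version
        of the drive and correlates more loosely."""
        rf = S.GroundTruthRF(centre=np.zeros(2), sigma=np.array([60.0, 60.0]))
        drive = S.rf_drive(noise_stimulus, rf)
        ca = S.ca_trace_from_drive(drive, noise_stimulus.refresh_rate)
        grad = RF.response_gradient(ca, S.MOVIE_RATE_HZ)
        t = np.arange(len(ca)) / S.MOVIE_RATE_HZ
        idx = np.clip((t * noise_stimulus.refresh_rate).astype(int),
                      0, len(drive) - 1)
        fwd = np.diff(ca) * S.MOVIE_RATE_HZ            # the generator's Euler step
        assert np.allclose(fwd, drive[idx[:-1]] - ca[:-1] / S.CA_TAU_S,
                           atol=1e-9)
        assert np.corrcoef(grad[2:-2], drive[idx][2:-2])[0, 1] >= 0.7


class TestBuildDesign:
    def test_lag_count_at_movie_rate(self, noise_stimulus):
        t = np.arange(200) / 31.25
        X, kept = RF.build_design(noise_stimulus, t)
        assert X.shape[1] == 15 * 20 * 32      # ceil(1.0 * 31.25) = 32 lags

    def test_constant_stimulus_gives_constant_columns(self):
        stim = S.DenseNoiseStimulus(np.ones((50, 3, 4)))
        t = np.arange(30) / 5.0
        with pytest.warns(UserWarning):
            X, kept = RF.build_design(stim, t)
        assert np.all(X == X[0:1, :])

    def test_single_pixel_lagged_copy(self):
        frames = np.zeros((20, 1, 1))
        frames[::3, 0, 0] = 1.0
        stim = S.DenseNoiseStimulus(frames, refresh_rate=5.0)
        t = np.arange(20) / 5.0
        X, kept = RF.build_design(stim, t, n_lags=2)
        seq = frames[:, 0, 0]
        assert np.array_equal(X[:, 0], seq[kept.astype(int)])
        assert np.array_equal(X[1:, 1], seq[kept.astype(int)][:-1])


class TestASDFit:
    def test_ridge_equivalence_zero_smoothness(self):
        rng = np.random.default_rng(3)
        n, H, W, nl = 200, 3, 3, 2
        X = rng.standard_normal((n, H * W * nl))
        y = X @ rng.standard_normal(H * W * nl) + rng.normal(0, 0.5, n)
        rho, nv = 0.7, 0.3
        k_asd = RF.asd_map(X, y, (H, W), nl, rho=rho,
                           delta_s=1e-8, delta_t=1e-8, noise_var=nv)
        k_ridge = np.linalg.solve(X.T @ X + nv * np.exp(rho) * np.eye(H * W * nl),
                                  X.T @ y)
        assert np.abs(k_asd.ravel() - k_ridge).max() < 1e-6

    def test_zero_response_zero_filter(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((100, 18))
        model = RF.asd_fit(X, np.zeros(100), (3, 3), 2)
        assert np.allclose(model.strf, 0.0)

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((150, 18))
        y = X @ rng.standard_normal(18) + rng.normal(0, 0.3, 150)
        m1 = RF.asd_fit(X, y, (3, 3), 2, max_iter=50)
        m2 = RF.asd_fit(X, 3.7 * y, (3, 3), 2, max_iter=50)
        assert np.allclose(3.7 * m1.strf, m2.strf, rtol=1e-9, atol=1e-12)

    def test_evidence_path_nondecreasing(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((120, 18))
        y = X @ rng.standard_normal(18) + rng.normal(0, 0.5, 120)
        model = RF.asd_fit(X, y, (3, 3), 2, max_iter=50)
        assert np.all(np.diff(model.evidence_path) >= 0)

    def test_recovery_beats_ridge_on_smooth_rf(self):
        """ASD spatial recovery r >= 0.9 at SNR 5, 1500 stimulus frames, and
        at least as accurate as a fixed-penalty ridge baseline on >= 8/10
        seeds (smooth planted Gaussian RF)."""
        wins, rs = 0, []
        for seed in range(10):
            stim = S.gen_dense_noise(duration=300.0, seed=200 + seed)
            rf = S.GroundTruthRF(centre=np.array([25.0, -10.0]),
                                 sigma=np.array([55.0, 55.0]))
            drive = S.rf_drive(stim, rf)
            rng = np.random.default_rng(300 + seed)
            y = drive + rng.normal(0, drive.std() / 5.0, drive.size)
            X, kept = RF.build_design(stim, stim.frame_times())
            y = y[kept]
            model = RF.asd_fit(X, y, (15, 20), 5, max_iter=40)
            sp = RF.svd_spatial_map(model.strf)
            truth = rf.spatial_map()
            r_asd = abs(np.corrcoef(sp.map.ravel(), truth.ravel())[0, 1])
            alpha = 10.0 * np.trace(X.T @ X) / X.shape[1]
            k_r = np.linalg.solve(X.T @ X + alpha * np.eye(X.shape[1]), X.T @ y)
            sp_r = RF.svd_spatial_map(k_r.reshape(15, 20, 5))
            r_ridge = abs(np.corrcoef(sp_r.map.ravel(), truth.ravel())[0, 1])
            rs.append(r_asd)
            wins += r_asd >= r_ridge
        assert np.median(rs) >= 0.9
        assert wins >= 8


class TestSVDSpatialMap:
    def test_rank_one_recovered(self):
        rng = np.random.default_rng(7)
        s = rng.standard_normal((6, 8))
        tk = np.array([1.0, 0.4, -0.2])
        strf = s[..., None] * tk[None, None, :]
        sp = RF.svd_spatial_map(strf)
        r = np.corrcoef(sp.map.ravel(), s.ravel())[0, 1]
        assert abs(r) > 1 - 1e-12
        assert sp.map.ravel()[np.argmax(np.abs(sp.map))] > 0

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(8)
        strf = (rng.standard_normal((5, 6, 1)) * np.ones((1, 1, 4))
                + 0.3 * rng.standard_normal((5, 6, 4)))
        sp = RF.svd_spatial_map(strf)
        M = strf.reshape(30, 4)
        v = rng.standard_normal(30)
        for _ in range(500):
            v = M @ (M.T @ v)
            v /= np.linalg.norm(v)
        r = abs(np.corrcoef(sp.map.ravel(), v)[0, 1])
        assert r > 1 - 1e-9

    def test_zero_strf_rejected(self):
        with pytest.raises(InvalidArgumentError):
            RF.svd_spatial_map(np.zeros((3, 3, 2)))

    def test_sign_product_preserved(self):
        rng = np.random.default_rng(9)
        s = -np.abs(rng.standard_normal((4, 4)))      # Off-like negative map
        tk = np.array([0.8, 0.3])
        strf = s[..., None] * tk[None, None, :]
        sp = RF.svd_spatial_map(strf)
        recon = sp.map[..., None] * sp.temporal[None, None, :]
        assert np.allclose(recon, strf, atol=1e-9)


class TestContours:
    @staticmethod
    def gaussian_rf(off=(0.0, 0.0), sigma=2.5):
        x = np.arange(20) - 9.5
        y = np.arange(15) - 7.0
        g = np.exp(-(((y[:, None] - off[1]) ** 2) +
                     ((x[None, :] - off[0]) ** 2)) / (2 * sigma ** 2))
        return RF.SpatialRF(map=g, temporal=np.array([1.0]), svd_sign=1)

    def test_single_gaussian_area_decreases_with_threshold(self):
        cs = RF.extract_contours(self.gaussian_rf())
        areas = []
        for thr in (0.60, 0.65, 0.70):
            assert len(cs[thr]) == 1
            areas.append(cs[thr][0].area)
        assert areas[0] > areas[1] > areas[2]

    def test_gaussian_contour_area_analytic(self):
        # level set of exp(-r²/2σ²) at t is a circle of radius σ√(-2 ln t)
        sigma = 2.5
        cs = RF.extract_contours(self.gaussian_rf(sigma=sigma))
        pitch = 30.0
        for thr in (0.60, 0.65, 0.70):
            r_px = sigma * np.sqrt(-2 * np.log(thr))
            expect = np.pi * (r_px * pitch) ** 2
            assert cs[thr][0].area == pytest.approx(expect, rel=0.05)

    def test_two_bumps_two_contours(self):
        x = np.arange(20) - 9.5
        y = np.arange(15) - 7.0
        g1 = np.exp(-((y[:, None] ** 2) + (x[None, :] + 5) ** 2) / 4.0)
        g2 = np.exp(-((y[:, None] ** 2) + (x[None, :] - 5) ** 2) / 4.0)
        sp = RF.SpatialRF(map=g1 + g2, temporal=np.array([1.0]), svd_sign=1)
        cs = RF.extract_contours(sp, thresholds=(0.60,))
        assert len(cs[0.60]) == 2

    def test_flat_map_no_contours(self):
        sp = RF.SpatialRF(map=np.zeros((15, 20)), temporal=np.array([1.0]),
                          svd_sign=1)
        cs = RF.extract_contours(sp)
        assert all(len(v) == 0 for v in cs.values())

    def test_threshold_validation(self):
        with pytest.raises(InvalidArgumentError):
            RF.extract_contours(self.gaussian_rf(), thresholds=(1.5,))


class TestIrregularityIndex:
    def test_convex_polygons_zero(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        assert RF.irregularity_index(square) == pytest.approx(0.0)
        t = np.linspace(0, 2 * np.pi, 100)
        circle = np.column_stack([np.cos(t), np.sin(t)])
        assert RF.irregularity_index(circle) < 1e-9

    def test_plus_pentomino_exact(self):
        # plus of 5 unit squares: A = 5; its convex hull is the corner-cut
        # octagon of area 7 (not the 3x3 bounding square)
        plus = np.array([[1, 0], [2, 0], [2, 1], [3, 1], [3, 2], [2, 2],
                         [2, 3], [1, 3], [1, 2], [0, 2], [0, 1], [1, 1],
                         [1, 0]], float)
        assert RF.irregularity_index(plus) == pytest.approx(1 - 5 / 7)

    def test_four_pointed_star_exact(self):
        # 3x3 bounding square with triangular notches of depth 2/3:
        # A = 9 - 4*(3*(2/3)/2) = 5, hull = 9, so Ii = 4/9
        star = np.array([[0, 0], [1.5, 2 / 3], [3, 0], [3 - 2 / 3, 1.5],
                         [3, 3], [1.5, 3 - 2 / 3], [0, 3], [2 / 3, 1.5],
                         [0, 0]])
        assert RF.irregularity_index(star) == pytest.approx(4 / 9)

    def test_marching_squares_circle_nearly_regular(self):
        cs = RF.extract_contours(TestContours.gaussian_rf(), thresholds=(0.60,))
        assert cs[0.60][0].irregularity < 0.01


class TestQualityFilter:
    def test_good_rf_passes(self):
        cs = RF.extract_contours(TestContours.gaussian_rf(), thresholds=(0.60,))
        rep = RF.rf_quality_filter(cs[0.60])
        assert rep.passed and rep.area > 1800

    def test_multiple_regions_fail(self):
        c = RF.extract_contours(TestContours.gaussian_rf(), (0.60,))[0.60][0]
        rep = RF.rf_quality_filter([c, c])
        assert not rep.passed and "multiple regions" in rep.reasons

    def test_small_contour_fails(self):
        cs = RF.extract_contours(TestContours.gaussian_rf(sigma=0.6), (0.60,))
        rep = RF.rf_quality_filter(cs[0.60])
        assert not rep.passed and "too small" in rep.reasons

    def test_no_contour_fails(self):
        rep = RF.rf_quality_filter([])
        assert not rep.passed and rep.reasons == ["no closed contour"]
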