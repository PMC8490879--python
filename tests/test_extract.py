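import dataclasses

import numpy as np
import pytest

from oracles import ols_brute, tsca_dense_top_component
from vsdi_retinomap.core import FrameStack, StimulusSchedule
from vsdi_retinomap.extract import (
    METHODS,
    AverageOfFrames,
    DelayedCorrelation,
    LinearModel,
    MaxCorrelationDelay,
    MPTParams,
    MultiParametricThresholding,
    TSCA,
    TSCAWithGLM,
    glm_denoise,
    glm_fit,
    tsca_solve_Q,
)
from vsdi_retinomap.kernels import (
    TemporalPriors,
    default_priors,
    delayed_kernels,
    make_design,
    make_kernel,
)
from vsdi_retinomap.simulate import SimConfig, simulate_experiment


def _gauss_kernel(frame_rate):
    return make_kernel("gaussian", sigma=1.0, frame_rate=frame_rate, duration=2.0)


class TestAOF:
    def test_single_frame_window(self):
        rng = np.random.default_rng(0)
        stack = FrameStack(rng.normal(size=(20, 3, 3)), 10.0)
        sched = StimulusSchedule(onsets=[0.5])
        res = AverageOfFrames(stack, sched, n_frames=1).fit()
        np.testing.assert_array_equal(res.raw_maps[0], stack.data[5])

    def test_hand_computed_mean(self):
        rng = np.random.default_rng(1)
        stack = FrameStack(rng.normal(size=(20, 2, 2)), 10.0)
        sched = StimulusSchedule(onsets=[0.3, 1.2])
        res = AverageOfFrames(stack, sched, n_frames=3).fit()
        for k, i0 in enumerate([3, 12]):
            expected = np.zeros((2, 2))
            for r in range(2):
                for c in range(2):
                    expected[r, c] = sum(stack.data[i0 + j, r, c] for j in range(3)) / 3
            np.testing.assert_allclose(res.raw_maps[k], expected, atol=1e-12)

    def test_constant_stack_constant_maps(self):
        stack = FrameStack(np.full((20, 3, 3), 4.0), 10.0)
        res = AverageOfFrames(stack, StimulusSchedule(onsets=[1.0])).fit()
        assert np.all(res.raw_maps == 4.0)
        np.testing.assert_array_equal(res.score_maps.maps, 0.0)  # constant -> zeros

    def test_truncated_window_warns(self):
        stack = FrameStack(np.ones((20, 2, 2)), 10.0)
        with pytest.warns(UserWarning, match="truncated"):
            AverageOfFrames(stack, StimulusSchedule(onsets=[1.9]), n_frames=5).fit()


class TestMPT:
    def test_noiseless_pixels_within_true_support(self, small_clean):
        stack, truth, sched = small_clean
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MultiParametricThresholding(stack, sched).fit()
        for k, onset in enumerate(sched.onsets):
            nz = res.raw_maps[k] > 0
            # z-scoring equalizes amplitudes, so any genuinely responding
            # pixel (positive response tail) may score
            assert np.all(truth.patterns[k][nz] > 0)
            if onset + 1.5 <= stack.duration:  # return window fits the record
                assert nz.any()

    def test_impossible_threshold_warns_all_zero(self, small_clean):
        stack, _, sched = small_clean
        params = MPTParams(abs_threshold=1e9)
        with pytest.warns(UserWarning, match="no pixel passed"):
            res = MultiParametricThresholding(stack, sched, params).fit()
        np.testing.assert_array_equal(res.raw_maps, 0.0)

    def test_disabled_cascade_is_peak_image(self, small_sim):
        stack, _, sched = small_sim
        params = MPTParams(
            abs_threshold=-np.inf,
            top_percent=100.0,
            peak_window=(-5.0, 5.0),
            baseline_value=np.inf,
            return_window=(0.0, 5.0),
        )
        res = MultiParametricThresholding(stack, sched, params).fit()
        from vsdi_retinomap.core import zscore_stack

        z = zscore_stack(stack).data
        half = sched.inter_stimulus_interval() / 2
        for k, onset in enumerate(sched.onsets):
            i0 = stack.frame_index(onset - half)
            i1 = stack.frame_index(onset + half) + 1
            np.testing.assert_allclose(
                res.raw_maps[k], z[i0:i1].max(axis=0), atol=1e-12
            )

    def test_param_validation(self):
        with pytest.raises(ValueError, match="top_percent"):
            MPTParams(top_percent=0.0)
        with pytest.raises(ValueError, match="peak_window"):
            MPTParams(peak_window=(1.0, 0.0))


class TestTmax:
    def _planted_stack(self):
        fs = 20.0
        T = 200
        sched = StimulusSchedule(onsets=[2.0, 6.0])
        g = _gauss_kernel(fs)
        gk = delayed_kernels(g, sched, T)
        rng = np.random.default_rng(0)
        data = rng.normal(scale=0.01, size=(T, 2, 2))
        data[:, 0, 0] += gk[0]
        data[:, 1, 1] += gk[1]
        return FrameStack(data, fs), sched, g

    def test_planted_pixels_recovered(self):
        stack, sched, g = self._planted_stack()
        res = MaxCorrelationDelay(stack, sched, g, corr_threshold=0.8).fit()
        assert res.raw_maps[0][0, 0] > 0.9
        assert res.raw_maps[1][1, 1] > 0.9
        assert res.raw_maps[1][0, 0] == 0.0

    def test_threshold_above_one_empty(self):
        stack, sched, g = self._planted_stack()
        with pytest.warns(UserWarning, match="no responsive"):
            res = MaxCorrelationDelay(stack, sched, g, corr_threshold=1.01).fit()
        np.testing.assert_array_equal(res.raw_maps, 0.0)

    def test_noiseless_core_assignment(self, small_clean):
        stack, truth, sched = small_clean
        res = MaxCorrelationDelay(stack, sched).fit()
        amap = res.raw_maps.argmax(axis=0) + 1
        scored = res.raw_maps.max(axis=0) > 0
        core = truth.patterns.max(axis=0) >= 0.5
        hit = scored[core] & (amap[core] == truth.assignment[core])
        assert hit.mean() >= 0.95


class TestCorr:
    def test_matched_pixel_scores_highest(self):
        fs = 20.0
        T = 200
        sched = StimulusSchedule(onsets=[2.0, 6.0])
        g = _gauss_kernel(fs)
        gk = delayed_kernels(g, sched, T)
        data = np.zeros((T, 1, 2))
        data[:, 0, 0] = gk[0]
        data[:, 0, 1] = gk[1]
        res = DelayedCorrelation(FrameStack(data, fs), sched, g).fit()
        # the matched stimulus wins per pixel
        assert res.raw_maps[0][0, 0] > res.raw_maps[1][0, 0]
        assert res.raw_maps[1][0, 1] > res.raw_maps[0][0, 1]

    def test_orthogonal_series_score_zero(self):
        fs = 50.0
        T = 500
        sched = StimulusSchedule(onsets=[5.0])
        g = _gauss_kernel(fs)
        t = np.arange(T) / fs
        data = np.zeros((T, 1, 1))
        data[:, 0, 0] = np.cos(2 * np.pi * 10.0 * t)  # far outside g's band
        res = DelayedCorrelation(FrameStack(data, fs), sched, g).fit()
        assert abs(res.raw_maps[0][0, 0]) < 1e-3

    def test_three_pixel_toy_brute_force(self):
        fs = 10.0
        T = 50
        sched = StimulusSchedule(onsets=[1.0, 3.0])
        g = _gauss_kernel(fs)
        gk = delayed_kernels(g, sched, T)
        rng = np.random.default_rng(5)
        data = rng.normal(size=(T, 3, 1))
        res = DelayedCorrelation(FrameStack(data, fs), sched, g).fit()
        for px in range(3):
            z = data[:, px, 0] - data[:, px, 0].mean()
            for k in range(2):
                gc = gk[k] - gk[k].mean()
                expected = sum(z[t] * gc[t] for t in range(T)) / T
                assert res.raw_maps[k][px, 0] == pytest.approx(expected, abs=1e-12)


class TestTscaSolveQ:
    def test_single_prior_closed_form(self):
        g = np.sin(np.linspace(0, 4, 30))
        priors = TemporalPriors(Cx_list=[np.outer(g, g)], Cy_list=[], gamma_x=1.0)
        Q = tsca_solve_Q(priors)
        np.testing.assert_allclose(Q, np.outer(g, g) / (g @ g), atol=1e-10)

    def test_constraints_satisfied(self):
        fs = 50.0
        g = _gauss_kernel(fs)
        sched = StimulusSchedule(onsets=[1.0, 3.0])
        priors = default_priors(sched, g, 150)
        Q = tsca_solve_Q(priors, stimulus_index=0)
        Cx = priors.Cx_list[0]
        assert np.sum(Q * Cx) == pytest.approx(
            priors.gamma_x * np.trace(Cx), rel=1e-8
        )
        for Cy in priors.Cy_list:
            assert np.sum(Q * Cy) == pytest.approx(
                priors.gamma_y * np.trace(Cy), rel=1e-8
            )

    def test_symmetric(self):
        fs = 50.0
        priors = default_priors(StimulusSchedule(onsets=[1.0]), _gauss_kernel(fs), 100)
        Q = tsca_solve_Q(priors)
        assert np.max(np.abs(Q - Q.T)) < 1e-12


class TestTSCA:
    def test_planted_rank_one_recovery(self):
        fs = 20.0
        T = 200
        sched = StimulusSchedule(onsets=[5.0])
        g = _gauss_kernel(fs)
        gk = delayed_kernels(g, sched, T)[0]
        rng = np.random.default_rng(3)
        pattern = np.abs(rng.normal(size=(6, 6)))
        data = gk[:, None, None] * pattern[None] + 1.0  # plus DC
        res = TSCA(FrameStack(data, fs), sched, kernel=g).fit()
        psi = res.raw_maps[0].ravel()
        cos = abs(psi @ pattern.ravel()) / (
            np.linalg.norm(psi) * np.linalg.norm(pattern)
        )
        assert cos > 0.999

    def test_reduced_solver_matches_dense_oracle(self):
        fs = 20.0
        T = 60
        sched = StimulusSchedule(onsets=[1.0])
        g = _gauss_kernel(fs)
        gk = delayed_kernels(g, sched, T)[0]
        rng = np.random.default_rng(4)
        data = rng.normal(size=(T, 4, 4)) + 3.0 * gk[:, None, None] * np.abs(
            rng.normal(size=(4, 4))
        )
        stack = FrameStack(data, fs)
        priors = default_priors(sched, g, T)
        res = TSCA(stack, sched, kernel=g, priors=priors).fit()
        eig_pkg = res.extras["components"][0].eigenvalue

        Z = stack.as_matrix()
        Zc = Z - Z.mean(axis=1, keepdims=True)
        Q = tsca_solve_Q(priors, 0)
        eig_dense, psi_dense = tsca_dense_top_component(Zc, Q)
        assert eig_pkg == pytest.approx(eig_dense, rel=1e-8)
        psi_pkg = res.raw_maps[0].ravel()
        psi_pkg = psi_pkg / np.linalg.norm(psi_pkg)
        assert abs(psi_pkg @ psi_dense) > 1 - 1e-8

    def test_component_sign_matches_kernel(self, small_clean):
        stack, truth, sched = small_clean
        res = TSCA(stack, sched).fit()
        for comp in res.extras["components"]:
            gk = delayed_kernels(
                _gauss_kernel(stack.frame_rate), sched, stack.n_frames
            )[comp.stimulus_index]
            c = np.corrcoef(comp.temporal, gk)[0, 1]
            assert c > 0

    def test_all_methods_postprocessed_contract(self, small_sim):
        stack, _, sched = small_sim
        for name, cls in METHODS.items():
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = cls(stack, sched).fit()
            maps = res.score_maps.maps
            assert maps.shape[0] == sched.n
            assert maps.min() >= 0.0 and maps.max() <= 1.0
            for m in maps:
                assert m.max() == pytest.approx(1.0) or np.all(m == 0.0)


class TestGLM:
    def _toy_design(self, T=80, fs=10.0):
        g = _gauss_kernel(fs)
        sched = StimulusSchedule(onsets=[2.0, 5.0])
        return make_design(sched, g, noise_freqs=(3.0,), harmonics=1, n_frames=T, frame_rate=fs)

    def test_exact_linear_combination_recovered(self):
        design = self._toy_design()
        rng = np.random.default_rng(6)
        beta_true = rng.normal(size=(design.p, 4))
        Y = design.X @ beta_true
        stack = FrameStack(Y.reshape(80, 2, 2), 10.0)
        beta_maps, resid = glm_fit(stack, design)
        np.testing.assert_allclose(
            beta_maps.reshape(design.p, 4), beta_true, atol=1e-9
        )
        assert np.abs(resid.data).max() < 1e-9

    def test_residuals_orthogonal_to_design(self):
        design = self._toy_design()
        rng = np.random.default_rng(7)
        stack = FrameStack(rng.normal(size=(80, 2, 2)), 10.0)
        _, resid = glm_fit(stack, design)
        R = resid.data.reshape(80, -1)
        assert np.abs(design.X.T @ R).max() < 1e-8

    def test_three_column_toy_vs_normal_equations(self):
        rng = np.random.default_rng(8)
        T = 40
        X = np.column_stack(
            [np.ones(T), np.linspace(-1, 1, T), rng.normal(size=T)]
        )
        y = rng.normal(size=T)
        beta_hand = ols_brute(X, y)
        from vsdi_retinomap.kernels import DesignMatrix

        design = DesignMatrix(X=X, roles=["intercept", "drift", "signal_1"])
        stack = FrameStack(np.tile(y[:, None, None], (1, 1, 1)), 10.0)
        beta_maps, _ = glm_fit(stack, design)
        np.testing.assert_allclose(beta_maps[:, 0, 0], beta_hand, atol=1e-10)


class TestGlmDenoise:
    def test_pure_tone_removed(self):
        fs = 50.0
        T = 500
        t = np.arange(T) / fs
        tone = np.sin(2 * np.pi * 3.0 * t)
        stack = FrameStack(np.tile(tone[:, None, None], (1, 3, 3)), fs)
        sched = StimulusSchedule(onsets=[1.0, 5.0])
        design = make_design(
            sched, _gauss_kernel(fs), n_frames=T, frame_rate=fs
        )
        out = glm_denoise(stack, design)
        assert np.sqrt(np.mean(out.data**2)) < 1e-6 * np.sqrt(np.mean(stack.data**2))

    def test_clean_signal_untouched(self, small_clean):
        stack, truth, sched = small_clean
        design = make_design(
            sched,
            _gauss_kernel(stack.frame_rate),
            n_frames=stack.n_frames,
            frame_rate=stack.frame_rate,
        )
        out = glm_denoise(stack, design)
        # no spectral content at the noise frequencies: near no-op
        rms_change = np.sqrt(np.mean((out.data - stack.data) ** 2))
        assert rms_change < 0.01 * np.sqrt(np.mean((stack.data - 1.0) ** 2))

    def test_band_power_reduced_on_noisy_simulation(self, small_sim):
        from scipy.signal import periodogram

        stack, _, sched = small_sim
        design = make_design(
            sched,
            _gauss_kernel(stack.frame_rate),
            n_frames=stack.n_frames,
            frame_rate=stack.frame_rate,
        )
        out = glm_denoise(stack, design)
        f, p_in = periodogram(
            stack.data.reshape(stack.n_frames, -1), fs=stack.frame_rate, axis=0
        )
        _, p_out = periodogram(
            out.data.reshape(stack.n_frames, -1), fs=stack.frame_rate, axis=0
        )
        band = (f >= 2.8) & (f <= 3.2)
        # discrete harmonics capture only part of the 0.4 Hz band
        assert p_in[band].sum() / p_out[band].sum() >= 1.2


class TestTscaGlm:
    def test_noiseless_equals_plain_tsca(self, small_clean):
        stack, _, sched = small_clean
        maps_a = TSCA(stack, sched).fit().score_maps.maps
        maps_b = TSCAWithGLM(stack, sched).fit().score_maps.maps
        for a, b in zip(maps_a, maps_b):
            cos = (a.ravel() @ b.ravel()) / (
                np.linalg.norm(a) * np.linalg.norm(b)
            )
            assert cos > 0.999
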