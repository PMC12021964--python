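"""Smoothing, drift correction and normalization against direct oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import enose as en
from enose.preprocess import SmootherConfig


def windowed_ols_smooth(x, window, degree):
    """Independent oracle: solve each centred window's least-squares
    polynomial directly and evaluate it at the window centre; edge windows
    use the first/last full window's polynomial evaluated at edge offsets."""
    T = len(x)
    half = window // 2
    out = np.empty(T)
    for t in range(T):
        lo = min(max(t - half, 0), T - window)
        idx = np.arange(lo, lo + window)
        coef = np.polyfit(idx - t, x[idx], degree)
        out[t] = np.polyval(coef, 0.0)
    return out


class TestSmoothing:
    def test_constant_is_fixed_point(self):
        x = np.full(120, 3.7)
        np.testing.assert_allclose(en.smooth_signal(x), x, atol=1e-9)

    def test_cubic_reproduced_exactly(self):
        t = np.arange(200, dtype=float)
        x = 0.001 * t**3 - 0.2 * t**2 + t - 4
        np.testing.assert_allclose(en.smooth_signal(x), x, rtol=1e-9)

    @pytest.mark.parametrize("window,degree", [(51, 3), (11, 2), (7, 1)])
    def test_matches_windowed_ols_oracle(self, rng, window, degree):
        x = rng.normal(0, 1, 150).cumsum()
        got = en.smooth_signal(x, SmootherConfig(window, degree))
        want = windowed_ols_smooth(x, window, degree)
        np.testing.assert_allclose(got, want, atol=1e-9)

    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    def test_linearity(self, a, b):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=(2, 80))
        cfg = SmootherConfig(11, 3)
        lhs = en.smooth_signal(a * x + b * y, cfg)
        rhs = a * en.smooth_signal(x, cfg) + b * en.smooth_signal(y, cfg)
        np.testing.assert_allclose(lhs, rhs, atol=1e-7)

    def test_short_signal_asks_for_more_samples(self):
        with pytest.raises(ValueError, match="buffer"):
            en.smooth_signal(np.ones(50))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SmootherConfig(50, 3)


class TestTuneSmoother:
    def test_singleton_grid(self, rng):
        cols = [rng.normal(size=120) for _ in range(2)]
        cfg = en.tune_smoother(cols, window_grid=[51], degree_grid=[3],
                               time_budget_ms=1e4)
        assert (cfg.window_length, cfg.poly_degree) == (51, 3)

    def test_beats_minimal_baseline_on_noisy_polynomials(self, rng):
        t = np.linspace(0, 1, 150)
        clean = [3 * t**2 - t + c for c in range(5)]
        cols = [c + rng.normal(0, 0.3, t.size) for c in clean]
        refs = [c + rng.normal(0, 0.3, t.size) for c in clean]
        grid_w, grid_d = [5, 11, 21, 51], [1, 2, 3]
        cfg = en.tune_smoother(cols, refs, grid_w, grid_d, time_budget_ms=1e4)

        def score(w, d):
            return np.mean([
                np.mean((en.smooth_signal(c, SmootherConfig(w, d)) - r) ** 2)
                for c, r in zip(cols, refs)
            ])

        # exhaustive-grid oracle agrees and the pick beats the (1,1) baseline
        best = min(
            ((w, d) for w in grid_w for d in grid_d if d < w),
            key=lambda wd: score(*wd),
        )
        assert (cfg.window_length, cfg.poly_degree) == best
        # the tuned pick beats the smallest valid grid candidate
        assert score(cfg.window_length, cfg.poly_degree) <= score(5, 1)

    def test_degree_ge_window_candidates_excluded(self, rng):
        cols = [rng.normal(size=100)]
        cfg = en.tune_smoother(cols, window_grid=[3], degree_grid=[3, 2],
                               time_budget_ms=1e4)
        assert cfg.poly_degree < cfg.window_length

    def test_zero_budget_reports_fastest_candidate(self, rng):
        with pytest.raises(ValueError, match="no feasible"):
            en.tune_smoother([rng.normal(size=100)], window_grid=[11],
                             degree_grid=[2], time_budget_ms=0.0)


class TestDrift:
    def test_exact_line_recovered(self):
        t = np.arange(300.0)
        d = en.estimate_drift(5.0 + 0.1 * t, fit_window=100)
        assert d.slope == pytest.approx(0.1, abs=1e-12)
        assert d.intercept == pytest.approx(5.0, abs=1e-10)

    def test_constant_has_zero_slope(self):
        d = en.estimate_drift(np.full(300, 2.5), fit_window=100)
        assert d.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = 7 - 0.03 * np.arange(300) + rng.normal(0, 0.5, 300)
        d = en.estimate_drift(x, fit_window=100)
        t = np.arange(100.0)
        A = np.vstack([t, np.ones(100)]).T
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ x[:100])
        assert d.slope == pytest.approx(slope, abs=1e-9)
        assert d.intercept == pytest.approx(intercept, abs=1e-9)

    def test_correct_drift_maps_line_to_constant(self):
        t = np.arange(300.0)
        x = 4.0 - 0.2 * t
        out = en.correct_drift(x, en.estimate_drift(x, 100))
        np.testing.assert_allclose(out, 4.0, atol=1e-8)

    def test_identity_when_drift_is_trivial(self):
        x = np.sin(np.arange(300) / 20) + 2
        d = en.DriftModel(slope=0.0, intercept=x[0])
        np.testing.assert_allclose(en.correct_drift(x, d), x, atol=1e-12)

    def test_step_preserved_trend_removed(self, rng):
        t = np.arange(300.0)
        step = np.where((t >= 100) & (t < 200), 10.0, 0.0)
        x = 50 - 0.05 * t + step
        d = en.estimate_drift(x, 100)
        out = en.correct_drift(x, d)
        # pointwise formula oracle
        np.testing.assert_allclose(
            out, x - (d.intercept + d.slope * t) + x[0], atol=1e-12
        )
        assert out[150] - out[50] == pytest.approx(10.0, abs=1e-8)

    def test_residual_slope_zero_on_fit_window(self, rng):
        x = 100 - 0.1 * np.arange(300) + rng.normal(0, 1, 300)
        out = en.correct_drift(x, en.estimate_drift(x, 100))
        resid_slope = np.polyfit(np.arange(100.0), out[:100], 1)[0]
        assert resid_slope == pytest.approx(0.0, abs=1e-9)


class TestNormalization:
    def test_mean_zero_std_one(self, rng):
        out = en.normalize_signal(rng.uniform(10, 20, 300))
        assert out.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.std() == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self, rng):
        x = en.normalize_signal(rng.normal(5, 2, 300))
        np.testing.assert_allclose(en.normalize_signal(x), x, atol=1e-9)

    @given(a=st.floats(0.1, 100), b=st.floats(-1000, 1000))
    def test_affine_invariance(self, a, b):
        x = np.random.default_rng(3).normal(size=200)
        np.testing.assert_allclose(
            en.normalize_signal(a * x + b), en.normalize_signal(x), atol=1e-7
        )

    def test_constant_signal_raises(self):
        with pytest.raises(ValueError, match="constant signal"):
            en.normalize_signal(np.full(300, 9.0))


class TestPreprocessSession:
    def test_equals_stagewise_composition(self, dataset):
        sig = dataset[0]
        out = en.preprocess_session(sig)
        for j in [0, 7, 14]:
            col = sig.values[:, j]
            sm = en.smooth_signal(col)
            dm = en.estimate_drift(sm, 100)
            corr = en.correct_drift(sm, dm)
            np.testing.assert_allclose(
                out.corrected_values[:, j], corr, atol=1e-9
            )
            np.testing.assert_allclose(
                out.values[:, j], en.normalize_signal(corr), atol=1e-9
            )
            assert out.drift_models[j].slope == pytest.approx(dm.slope)

    def test_every_column_standardized(self, processed):
        for sig in processed[:4]:
            np.testing.assert_allclose(sig.values.mean(0), 0, atol=1e-9)
            np.testing.assert_allclose(sig.values.std(0), 1, atol=1e-9)

    def test_deterministic(self, dataset):
        a = en.preprocess_session(dataset[3])
        b = en.preprocess_session(dataset[3])
        np.testing.assert_array_equal(a.values, b.values)

    def test_constant_session_fails_in_normalize(self):
        sig = en.OdorSignal(np.ones((300, 15)), "flat")
        with pytest.raises(ValueError, match="normalization failed"):
            en.preprocess_session(sig)

    def test_fit_window_must_stay_in_phase_a(self, dataset):
        with pytest.raises(ValueError, match="phase A"):
            en.preprocess_session(dataset[0], fit_window=150)

    def test_linear_drift_removed_up_to_constant(self, signatures):
        noise = en.SessionNoiseSpec(baseline=500, drift_slope=-0.3,
                                    noise_sd=0.0, seed=0)
        clean = en.SessionNoiseSpec(baseline=500, drift_slope=0.0,
                                    noise_sd=0.0, seed=0)
        drifted = en.preprocess_session(
            en.simulate_session(signatures[0], noise), normalize=False
        )
        ref = en.preprocess_session(
            en.simulate_session(signatures[0], clean), normalize=False
        )
        diff = drifted.values - ref.values
        assert np.ptp(diff, axis=0).max() < 1e-6
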