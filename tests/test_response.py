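import numpy as np
import pytest
from scipy import stats

from floodshift import AnnualSeries, aicc, ar1_loglik, fit, model_mean, select_best
from floodshift.response import FAMILIES, residual_lag1, _whiten
from floodshift.synth import gen_annual_series


def make_series(values, start=1):
    values = np.asarray(values, dtype=float)
    return AnnualSeries(labels=tuple(range(start, start + len(values))),
                        values=values)


class TestModelMean:
    def test_step_mean_evaluation(self):
        p = {"a": 1.0, "c": -2.0}
        assert model_mean("step_mean", p, [4.0], tau=5.0)[0] == 1.0
        assert model_mean("step_mean", p, [5.0], tau=5.0)[0] == -1.0

    def test_sigmoid_midpoint_identity(self):
        p = {"a": 1.0, "c": 4.0, "t0": 10.0, "s": 2.0}
        assert model_mean("sigmoid", p, [10.0])[0] == pytest.approx(3.0)

    def test_linear_linear_nests_linear(self):
        t = np.arange(1.0, 21.0)
        nested = model_mean("linear_linear",
                            {"a": 2.0, "b": 0.5, "a2": 2.0, "b2": 0.5},
                            t, tau=10.0)
        plain = model_mean("linear", {"a": 2.0, "b": 0.5}, t)
        assert np.allclose(nested, plain)

    def test_sigmoid_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            model_mean("sigmoid", {"a": 0, "c": 1, "t0": 5, "s": 0}, [1.0])


class TestAicc:
    def test_direct_arithmetic(self):
        # -2(-10) + 2*2 + 2*2*3/(14-3) = 24 + 12/11
        assert aicc(-10.0, 2, 14) == pytest.approx(24 + 12 / 11)

    def test_approaches_plain_aic_for_large_n(self):
        assert aicc(-10.0, 2, 10**6) == pytest.approx(24.0, abs=1e-4)

    def test_smaller_k_wins_at_equal_likelihood(self):
        assert aicc(-10.0, 2, 14) < aicc(-10.0, 3, 14)

    def test_undefined_when_sample_too_small(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 13, 14)


class TestFit:
    def test_noise_free_step_exact(self):
        y = np.concatenate([np.zeros(8), np.full(8, 5.0)])
        res = fit(make_series(y), "step_mean", tau=9.0)
        assert res.params["a"] == pytest.approx(0.0, abs=1e-10)
        assert res.params["c"] == pytest.approx(5.0, abs=1e-10)
        assert np.sum(res.residuals**2) == pytest.approx(0.0, abs=1e-18)

    def test_linear_closed_form(self):
        t = np.arange(1.0, 31.0)
        res = fit(make_series(2.0 + 0.5 * t), "linear")
        assert res.params["a"] == pytest.approx(2.0, abs=1e-10)
        assert res.params["b"] == pytest.approx(0.5, abs=1e-10)

    def test_ar1_reduces_to_iid_on_white_noise(self):
        s, _ = gen_annual_series("linear", {"a": 1.0, "b": 0.1}, 200, 1.0, seed=4)
        iid = fit(s, "linear", error="iid")
        ar1 = fit(s, "linear", error="ar1")
        assert abs(ar1.phi) < 0.15
        for k in iid.params:
            assert ar1.params[k] == pytest.approx(iid.params[k], abs=1e-2)

    def test_k_counts_every_estimated_quantity(self):
        y = np.arange(30.0) + np.sin(np.arange(30))
        s = make_series(y)
        assert fit(s, "linear").k == 3                       # a, b, variance
        assert fit(s, "linear", error="ar1").k == 4          # + phi
        # a, c, two variances, phi
        assert fit(s, "step_mean", tau=15.0, error="ar1_hetero").k == 5

    def test_hetero_variance_ratio_recovered(self):
        rng = np.random.default_rng(8)
        y = np.concatenate([rng.normal(0, 0.5, 20), rng.normal(4, 2.0, 20)])
        res = fit(make_series(y), "step_mean", tau=21.0, error="ar1_hetero")
        assert res.variance_ratio == pytest.approx((2.0 / 0.5) ** 2, rel=0.6)

    def test_sigmoid_recovers_sharp_transition(self):
        s, _ = gen_annual_series("sigmoid",
                                 {"a": 0.0, "c": 4.0, "t0": 16.0, "s": 1.0},
                                 30, 0.05, seed=2)
        res = fit(s, "sigmoid")
        assert res.params["t0"] == pytest.approx(16.0, abs=0.5)
        assert res.params["c"] == pytest.approx(4.0, abs=0.3)


class TestAr1Loglik:
    def test_matches_dense_multivariate_normal(self):
        """Closed-form tridiagonal AR(1) likelihood equals a dense MVN oracle."""
        rng = np.random.default_rng(11)
        for n in (5, 17, 50):
            r = rng.normal(size=n)
            phi = rng.uniform(-0.8, 0.8)
            sigma2 = rng.uniform(0.5, 2.0)
            w = np.where(np.arange(n) >= n // 2, 1.7, 1.0)
            for weights in (None, w):
                S = np.diag(weights if weights is not None else np.ones(n))
                R = phi ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
                cov = sigma2 * S @ R @ S
                expected = stats.multivariate_normal(np.zeros(n), cov).logpdf(r)
                assert ar1_loglik(r, phi, sigma2, weights) == pytest.approx(
                    expected, abs=1e-8)

    def test_whitening_quadratic_form(self):
        rng = np.random.default_rng(12)
        r = rng.normal(size=9)
        phi = 0.55
        R = phi ** np.abs(np.subtract.outer(np.arange(9), np.arange(9)))
        z = _whiten(r, phi)
        assert np.sum(z**2) / (1 - phi**2) == pytest.approx(
            r @ np.linalg.solve(R, r), abs=1e-10)


class TestResidualLag1:
    def test_exact_fit_zero_autocorrelation(self):
        r1, flag = residual_lag1(np.zeros(20))
        assert r1 == 0.0 and not flag

    def test_ar_residuals_flagged(self):
        flags = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = np.empty(100)
            x[0] = rng.normal()
            for i in range(1, 100):
                x[i] = 0.7 * x[i - 1] + rng.normal()
            flags += residual_lag1(x)[1]
        assert flags >= 47  # >=95% power at phi = 0.7

    def test_white_noise_size(self):
        flags = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            flags += residual_lag1(rng.normal(size=100))[1]
        assert flags <= 5


class TestSelectBest:
    def test_noise_free_step_selects_step_mean(self):
        y = np.concatenate([np.zeros(8), np.full(8, 5.0)])
        comp = select_best(make_series(y), tau=9.0)
        assert comp.best_family == "step_mean"

    def test_white_noise_prefers_null(self):
        wins = 0
        for seed in range(50):
            s, _ = gen_annual_series("null", {"a": 0.0}, 30, 1.0, seed=seed)
            wins += select_best(s, tau=16.0).best_family == "null"
        assert wins >= 30  # >=60%

    def test_rss_nesting_linear_vs_segmented(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            s = make_series(rng.normal(size=20))
            rss_lin = np.sum(fit(s, "linear").residuals ** 2)
            rss_seg = np.sum(fit(s, "linear_linear", tau=10.0).residuals ** 2)
            assert rss_seg <= rss_lin + 1e-10

    def test_ranking_invariant_to_constant_shift(self):
        s, _ = gen_annual_series("step_mean", {"a": 0.0, "c": 4.0}, 30, 1.0,
                                 seed=5, tau=16)
        base = select_best(s, tau=16.0)
        shifted = select_best(make_series(s.values + 100.0), tau=16.0)
        assert [f.family for f in base.fits] == [f.family for f in shifted.fits]
        assert shifted.best.params["c"] == pytest.approx(
            base.best.params["c"], abs=1e-6)

    def test_autocorrelated_residuals_trigger_ar1_refit(self):
        s, _ = gen_annual_series("null", {"a": 0.0}, 60, 1.0, phi=0.8, seed=9)
        comp = select_best(s, tau=30.0)
        assert comp.autocorr_flagged
        assert comp.error_structure == "ar1"
        assert comp.best.phi is not None

    def test_free_tau_profiles_change_point(self):
        y = np.concatenate([np.zeros(10), np.full(10, 5.0)])
        comp = select_best(make_series(y), free_tau=True)
        assert comp.best_family == "step_mean"
        step = [f for f in comp.fits if f.family == "step_mean"][0]
        assert step.tau == pytest.approx(11.0)
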