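import numpy as np
import pytest
import statsmodels.api as sm
from scipy import integrate
from scipy.special import expit, logit
from scipy.stats import norm

from boarrest.glmm import (GlmmFit, _ll_zt_poisson, _make_nll, _NestedData,
                           build_design, fit_glmm, marginal_r2,
                           predict_response, rvs_zt_poisson,
                           simulate_glmm_response, zt_poisson_mean)


class TestClosedForms:
    def test_intercept_only_logit(self):
        y = np.r_[np.ones(1), np.zeros(1000)]
        fit = fit_glmm(np.ones((1001, 1)), y, "binomial")
        assert fit.coef[0] == pytest.approx(logit(1 / 1001), abs=1e-6)

    def test_zero_truncated_mean_at_lambda_one(self):
        assert zt_poisson_mean(1.0) == pytest.approx(1.0 / (1 - np.exp(-1)), abs=1e-12)
        assert zt_poisson_mean(1.0) == pytest.approx(1.582, abs=1e-3)

    def test_zt_sampler_matches_truncated_mean(self, rng):
        draws = rvs_zt_poisson(np.full(20000, 1.0), rng)
        assert draws.min() >= 1
        assert draws.mean() == pytest.approx(zt_poisson_mean(1.0), abs=0.02)


class TestGlmOracle:
    """With a single group the random variance is pinned at zero and the fit
    must agree with an ordinary IRLS GLM."""

    @pytest.mark.parametrize("family", ["binomial", "zt_poisson", "gamma_log"])
    def test_matches_glm_at_zero_variance(self, family, rng):
        n = 1500
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        if family == "binomial":
            y = simulate_glmm_response(X, [0.4, -0.7], family, rng)
            sm_fam = sm.families.Binomial()
        elif family == "zt_poisson":
            # large lambda so the truncation mass is numerically negligible
            y = simulate_glmm_response(X, [3.0, 0.2], family, rng)
            sm_fam = sm.families.Poisson()
        else:
            y = simulate_glmm_response(X, [0.5, 0.4], family, rng, shape=2.0)
            sm_fam = sm.families.Gamma(link=sm.families.links.Log())
        fit = fit_glmm(X, y, family, site=np.zeros(n), animal=np.zeros(n))
        oracle = sm.GLM(y, X, family=sm_fam).fit(tol=1e-12).params
        tol = 1e-4 if family == "zt_poisson" else 1e-6
        assert np.abs(fit.coef - oracle).max() < tol
        assert fit.var_components == {"site": 0.0, "animal": 0.0}

    def test_zt_reduces_to_poisson_when_truncation_negligible(self, rng):
        n = 800
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        lam = np.exp(X @ np.array([3.0, 0.2]))
        y = rng.poisson(lam)
        assert (y >= 1).all()
        fit = fit_glmm(X, y, "zt_poisson")
        oracle = sm.GLM(y, X, family=sm.families.Poisson()).fit(tol=1e-12).params
        assert np.abs(fit.coef - oracle).max() < 1e-4


class TestLaplaceLikelihood:
    def test_against_brute_force_integration(self, rng):
        site = np.repeat([0, 0, 1, 1], 25)
        anim = np.repeat([0, 1, 2, 3], 25)
        X = np.column_stack([np.ones(100), rng.normal(size=100)])
        y = rng.integers(1, 5, 100).astype(float)
        beta = np.array([0.4, 0.3])
        sds, sda = 0.5, 0.7

        def brute():
            eta0 = X @ beta
            total = 0.0
            for s in range(2):
                def f(u):
                    val = 1.0
                    for a in np.unique(anim[site == s]):
                        m = anim == a
                        iv, _ = integrate.quad(
                            lambda v: np.exp(_ll_zt_poisson(
                                y[m], eta0[m] + sds * u + sda * v).sum()) * norm.pdf(v),
                            -8, 8)
                        val *= iv
                    return val * norm.pdf(u)
                iu, _ = integrate.quad(f, -8, 8)
                total += np.log(iu)
            return -total

        data = _NestedData(X, y, site, anim, None)
        nll = _make_nll(data, "zt_poisson", True, True, False)
        approx = nll(np.r_[beta, np.log(sds), np.log(sda)])
        assert approx == pytest.approx(brute(), rel=1e-3)

    @pytest.mark.parametrize("family,beta", [
        ("binomial", [-0.5, 0.8]), ("zt_poisson", [0.3, 0.5]),
        ("gamma_log", [0.3, 0.5])])
    def test_parameter_recovery_smoke(self, family, beta):
        # full 100-replicate coverage lives in the acceptance suite
        covered = 0
        for rep in range(5):
            rng = np.random.default_rng(200 + rep)
            anim = np.repeat(np.arange(20), 100)
            site = anim // 4
            X = np.column_stack([np.ones(2000), rng.normal(size=2000)])
            y = simulate_glmm_response(X, beta, family, rng, site=site,
                                       animal=anim, sd_site=0.4, sd_animal=0.5)
            fit = fit_glmm(X, y, family, site=site, animal=anim)
            covered += abs(fit.coef[1] - beta[1]) < 2 * fit.se[1]
            assert (fit.se > 0).all()
            assert fit.var_components["animal"] >= 0
        assert covered >= 4

    def test_no_relocations_triggers_penalized_fallback(self, rng):
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = np.zeros(n)
        fit = fit_glmm(X, y, "binomial")
        assert fit.penalized

    def test_rank_deficient_design_drops_aliased_column(self, rng):
        n = 300
        z = rng.normal(size=n)
        X = np.column_stack([np.ones(n), z, 2 * z])
        y = simulate_glmm_response(X[:, :2], [0.2, 0.5], "binomial", rng)
        fit = fit_glmm(X, y, "binomial", term_names=["Intercept", "z", "z2"])
        assert len(fit.coef) == 2


class TestDiagnostics:
    def test_marginal_r2_zero_for_intercept_only(self, rng):
        n = 500
        X = np.ones((n, 1))
        y = simulate_glmm_response(X, [0.3], "binomial", rng)
        fit = fit_glmm(X, y, "binomial")
        assert marginal_r2(fit) == 0.0

    def test_marginal_r2_matches_plugin_formula(self, rng):
        # binomial with known beta and group variance 0.5: compare against
        # the formula evaluated at the true parameters
        n, g = 5000, 50
        anim = np.repeat(np.arange(g), n // g)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([0.0, 1.0])
        y = simulate_glmm_response(X, beta, "binomial", rng, animal=anim,
                                   sd_animal=np.sqrt(0.5))
        fit = fit_glmm(X, y, "binomial", animal=anim)
        truth = 1.0 / (1.0 + 0.5 + np.pi ** 2 / 3)
        assert marginal_r2(fit) == pytest.approx(truth, abs=0.05)

    def test_r2_bounded(self, rng):
        for rep in range(20):
            n = 200
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = simulate_glmm_response(X, rng.normal(0, 0.5, 2), "binomial", rng)
            fit = fit_glmm(X, y, "binomial")
            assert 0.0 <= marginal_r2(fit) <= 1.0


class TestPrediction:
    def _fit(self, rng):
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = simulate_glmm_response(X, [0.0, 1.0], "binomial", rng)
        return fit_glmm(X, y, "binomial"), X

    def test_zero_linear_predictor_gives_half(self):
        fit = GlmmFit("binomial", ["Intercept"], np.array([0.0]),
                      np.array([0.1]), np.array([[0.01]]),
                      {"site": 0, "animal": 0}, None, 0.0, True, 10)
        p, lo, hi = predict_response(fit, np.array([1.0]))
        assert p == 0.5

    def test_ci_ordering(self, rng):
        fit, X = self._fit(rng)
        p, lo, hi = predict_response(fit, np.array([1.0, 0.5]))
        assert lo < p < hi

    def test_prediction_at_mean_profile_close_to_mean_fitted(self, rng):
        fit, X = self._fit(rng)
        p, *_ = predict_response(fit, X.mean(axis=0))
        mean_fitted = expit(X @ fit.coef).mean()
        assert abs(p - mean_fitted) < 0.02   # Jensen gap tolerance

    def test_missing_covariate_rejected(self, rng):
        fit, X = self._fit(rng)
        with pytest.raises(ValueError):
            predict_response(fit, np.array([1.0]))


class TestDesignBuilder:
    def test_interaction_terms(self):
        import pandas as pd
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        X, names = build_design(df, ["a", "b", "a:b"])
        assert names == ["Intercept", "a", "b", "a:b"]
        assert X[1, 3] == 8.0
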