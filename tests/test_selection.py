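import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from boarrest.glmm import GlmmFit
from boarrest.selection import (CvConfig, _boyce_corr, boyce_cv,
                                home_range_90kde, sample_available,
                                selection_ratio, standardize)


class TestHomeRange:
    def test_gaussian_contour_area_matches_analytic(self, rng):
        # 90% contour of an isotropic Gaussian has radius sigma*sqrt(-2 ln 0.1)
        sigma = 500.0
        xy = rng.normal(0, sigma, (10_000, 2))
        hr = home_range_90kde(xy[:, 0], xy[:, 1])
        analytic = np.pi * (np.sqrt(-2 * np.log(0.1)) * sigma) ** 2
        assert abs(hr.area_m2 - analytic) / analytic < 0.10

    def test_mask_mass_self_consistent(self, rng):
        xy = rng.normal(0, 300.0, (5000, 2))
        hr = home_range_90kde(xy[:, 0], xy[:, 1])
        # fraction of fixes inside the 90% contour is close to 0.9
        inside = hr.contains_points(xy[:, 0], xy[:, 1])
        assert 0.85 <= inside.mean() <= 0.95

    def test_degenerate_fixes_rejected(self):
        x = np.zeros(100)
        with pytest.raises(ValueError):
            home_range_90kde(x, x)

    def test_too_few_fixes_rejected(self, rng):
        xy = rng.normal(0, 100, (10, 2))
        with pytest.raises(ValueError):
            home_range_90kde(xy[:, 0], xy[:, 1])


class TestAvailabilitySampling:
    def _home_range(self, rng):
        xy = rng.normal(0, 400.0, (5000, 2))
        return home_range_90kde(xy[:, 0], xy[:, 1])

    def test_samples_inside_polygon(self, rng):
        hr = self._home_range(rng)
        pts = sample_available(hr, 2000, rng)
        assert hr.contains_points(pts[:, 0], pts[:, 1]).all()

    def test_uniformity_chi_square_on_square_range(self, rng):
        from boarrest.selection import HomeRange
        # a synthetic square home range built directly from a full mask
        gx = np.arange(0.0, 1050.0, 50.0)
        gy = np.arange(0.0, 1050.0, 50.0)
        mask = np.ones((len(gx) - 1, len(gy) - 1), dtype=bool)
        from shapely.geometry import box
        hr = HomeRange("a", box(0, 0, 1000, 1000), (50, 50), 50.0,
                       _gx=gx, _gy=gy, _mask=mask)
        pts = sample_available(hr, 10_000, rng)
        qx = (pts[:, 0] > 500).astype(int)
        qy = (pts[:, 1] > 500).astype(int)
        counts = np.bincount(qx * 2 + qy, minlength=4)
        assert chisquare(counts).pvalue > 0.01

    def test_same_seed_identical_sample(self):
        rng = np.random.default_rng(3)
        hr = self._home_range(rng)
        a = sample_available(hr, 500, np.random.default_rng(7))
        b = sample_available(hr, 500, np.random.default_rng(7))
        assert np.array_equal(a, b)


def _simulate_rsf_data(rng, beta_veg=0.0, beta_road=0.0, n_used=200,
                       n_per_used=30):
    """Used/available rows from an exponential RSF over synthetic covariates."""
    n_avail = n_used * n_per_used
    n_cand = n_avail + 50 * n_used
    veg = (rng.uniform(size=n_cand) < 0.4).astype(int)
    d_road = rng.exponential(1.0, n_cand)
    d_village = rng.exponential(1.0, n_cand)
    w = np.exp(beta_veg * veg + beta_road * d_road)
    used_idx = rng.choice(n_cand, n_used, replace=False, p=w / w.sum())
    avail_idx = rng.choice(n_cand, n_avail, replace=False)
    idx = np.r_[used_idx, avail_idx]
    return pd.DataFrame({
        "used": np.r_[np.ones(n_used), np.zeros(n_avail)].astype(int),
        "animal_id": "a1", "site_id": "s1",
        "veg": veg[idx], "d_road": d_road[idx], "d_village": d_village[idx]})


def neutral_sr_curve(rng, n_used=2000, n_per=15):
    """Fit an RSF on neutrally sampled used points; SR curve over the
    central 95% of each covariate (others at their mean), both veg classes.
    Also asserts each slope is within 2 SE of 0."""
    from boarrest.selection import fit_rsf
    df = _simulate_rsf_data(rng, n_used=n_used, n_per_used=n_per)
    dfs, _ = standardize(df)
    fit = fit_rsf(dfs)
    avail = dfs[dfs["used"] == 0]
    grids = []
    for veg in (0, 1):
        for c in ("d_road", "d_village"):
            other = "d_village" if c == "d_road" else "d_road"
            grid = np.linspace(avail[c].quantile(0.025),
                               avail[c].quantile(0.975), 25)
            grids.append(pd.DataFrame({"veg": veg, c: grid, other: 0.0}))
    profile = pd.concat(grids, ignore_index=True)
    return selection_ratio(fit, profile, n_used=n_used,
                           n_available=n_used * n_per), fit


class TestRsfAndSelectionRatio:
    def test_neutral_sampling_slopes_near_zero_and_sr_near_one(self):
        # neutrality is a statement about the estimand: the replicate-
        # averaged SR curve must sit within +-0.1 of 1 everywhere, and each
        # fit's slopes within 2 SE of 0
        curves, covered, n_slopes = [], 0, 0
        for rep in range(5):
            rng = np.random.default_rng(500 + rep)
            sr, fit = neutral_sr_curve(rng, n_used=2000, n_per=15)
            curves.append(sr["sr"].to_numpy())
            for j in range(1, len(fit.coef)):
                n_slopes += 1
                covered += abs(fit.coef[j]) < 2 * fit.se[j]
        assert covered / n_slopes >= 0.9   # ~95% nominal coverage of zero
        mean_curve = np.mean(curves, axis=0)
        assert ((mean_curve >= 0.9) & (mean_curve <= 1.1)).all()

    def test_known_coefficient_recovered(self, rng):
        from boarrest.selection import fit_rsf
        df = _simulate_rsf_data(rng, beta_veg=1.0)
        dfs, _ = standardize(df)
        fit = fit_rsf(dfs)
        j = fit.term_names.index("veg")
        assert abs(fit.coef[j] - 1.0) < 2 * fit.se[j]

    def test_sr_exact_algebra(self):
        # eta(x) = log(n_used / n_available) must give SR exactly 1
        fit = GlmmFit("binomial", ["Intercept", "veg", "d_road", "d_village",
                                   "veg:d_road", "veg:d_village"],
                      np.array([np.log(200 / 6000.0), 0, 0, 0, 0, 0]),
                      np.ones(6), np.eye(6) * 1e-4,
                      {"site": 0, "animal": 0}, None, 0.0, True, 10)
        profile = pd.DataFrame({"veg": [0], "d_road": [0.0], "d_village": [0.0]})
        sr = selection_ratio(fit, profile, n_used=200, n_available=6000)
        assert sr.loc[0, "sr"] == pytest.approx(1.0)

    def test_sr_monotone_without_interaction(self):
        fit = GlmmFit("binomial", ["Intercept", "veg", "d_road", "d_village",
                                   "veg:d_road", "veg:d_village"],
                      np.array([-3.0, 0.0, 0.7, 0.0, 0.0, 0.0]),
                      np.ones(6), np.eye(6) * 1e-4,
                      {"site": 0, "animal": 0}, None, 0.0, True, 10)
        grid = pd.DataFrame({"veg": 0, "d_road": np.linspace(0, 3, 20),
                             "d_village": 0.0})
        sr = selection_ratio(fit, grid, 200, 6000)
        assert (np.diff(sr["sr"]) > 0).all()

    def test_nonconverged_fit_refused(self):
        fit = GlmmFit("binomial", ["Intercept"], np.array([0.0]), np.ones(1),
                      np.eye(1), {"site": 0, "animal": 0}, None, 0.0, False, 10)
        with pytest.raises(ValueError):
            selection_ratio(fit, pd.DataFrame({"veg": [0], "d_road": [0.0],
                                               "d_village": [0.0]}), 1, 1)


class TestBoyceCv:
    def test_true_scores_give_high_correlation(self, rng):
        df = _simulate_rsf_data(rng, beta_veg=1.5, beta_road=1.0, n_used=400)
        truth = lambda d: 1.5 * d["veg"].to_numpy() + 1.0 * d["d_road"].to_numpy()
        out = boyce_cv(df, CvConfig(n_reps=5, seed=1), score_override=truth)
        assert out["mean"] >= 0.9

    def test_random_scores_near_zero(self, rng):
        df = _simulate_rsf_data(rng, beta_veg=1.5, n_used=300)
        noise_rng = np.random.default_rng(99)
        noise = lambda d: noise_rng.normal(size=len(d))
        out = boyce_cv(df, CvConfig(n_reps=20, seed=2), score_override=noise)
        assert abs(out["mean"]) <= 0.3

    def test_deterministic_given_seed(self, rng):
        df = _simulate_rsf_data(rng, beta_veg=1.0, n_used=100, n_per_used=10)
        a = boyce_cv(df, CvConfig(n_reps=3, seed=5))
        b = boyce_cv(df, CvConfig(n_reps=3, seed=5))
        assert a == b

    def test_refit_cv_beats_shuffled_covariates(self, rng):
        df = _simulate_rsf_data(rng, beta_veg=1.5, beta_road=0.8, n_used=300)
        good = boyce_cv(df, CvConfig(n_reps=5, seed=3))
        shuffled = df.copy()
        perm = rng.permutation(len(df))
        for c in ("veg", "d_road", "d_village"):
            shuffled[c] = shuffled[c].to_numpy()[perm]
        bad = boyce_cv(shuffled, CvConfig(n_reps=5, seed=3))
        assert good["mean"] > bad["mean"]

    def test_empty_bin_merging(self):
        # a gap in the middle of the score range empties some bins, which
        # are merged with their lower neighbor rather than breaking the rank
        used = np.r_[np.linspace(0.0, 0.35, 20), np.linspace(0.65, 1.0, 40)]
        avail = np.r_[np.linspace(0.0, 0.35, 300), np.linspace(0.65, 1.0, 300)]
        rho = _boyce_corr(used, avail, 10)
        assert not np.isnan(rho)
        assert rho > 0   # higher scores are relatively enriched in used
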