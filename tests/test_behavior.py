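from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from boarrest import behavior
from boarrest.data_io import AnimalRecord
from boarrest.glmm import (build_design, fit_glmm, predict_response,
                           rvs_zt_poisson)
from boarrest.landscape import HS_HUNTING_DAY, HS_NONHUNTING, NHS


def make_records(lengths):
    recs = {}
    for aid, days in lengths.items():
        t0 = datetime(2021, 1, 1)
        recs[aid] = AnimalRecord(aid, "area0", "male", t0 - timedelta(days=3),
                                 t0, t0 + timedelta(days=days))
    return recs


def make_sites(rows):
    return pd.DataFrame([dict(site_id=i, animal_id=r.get("animal_id", "a1"),
                              x=0.0, y=0.0, study_site="area0",
                              veg=r.get("veg", 1),
                              d_village_m=r.get("d_village_m", 500.0),
                              d_road_m=r.get("d_road_m", 300.0),
                              n_visits_NHS=r.get("nhs", 0),
                              n_visits_HS=r.get("hs", 0))
                         for i, r in enumerate(rows)])


class TestRevisitDataset:
    def test_zero_visit_sites_truncated(self):
        sites = make_sites([dict(nhs=3), dict(nhs=0, hs=2)])
        recs = make_records({"a1": 120})
        nhs = behavior.build_revisit_dataset(sites, recs, "NHS")
        assert list(nhs["n_visits"]) == [3]

    def test_both_season_site_enters_both_tables(self):
        sites = make_sites([dict(nhs=2, hs=1)])
        recs = make_records({"a1": 120})
        assert len(behavior.build_revisit_dataset(sites, recs, "NHS")) == 1
        assert len(behavior.build_revisit_dataset(sites, recs, "HS")) == 1

    def test_survey_length_enters_logged(self):
        sites = make_sites([dict(nhs=1)])
        recs = make_records({"a1": 100})
        out = behavior.build_revisit_dataset(sites, recs, "NHS")
        assert out.loc[0, "log_survey_length"] == pytest.approx(np.log(100.0))

    def test_missing_survey_length_rejected(self):
        sites = make_sites([dict(nhs=1)])
        with pytest.raises(ValueError):
            behavior.build_revisit_dataset(sites, {}, "NHS")


class TestRevisitationFit:
    def _simulate_rows(self, rng, beta_dv):
        n = 400
        rows = pd.DataFrame({
            "animal_id": np.repeat([f"a{i}" for i in range(8)], n // 8),
            "study_site": np.repeat(["s0", "s1"], n // 2),
            "veg": rng.integers(0, 2, n),
            "d_village": rng.exponential(1.0, n),
            "d_road": rng.exponential(1.0, n),
            "log_survey_length": np.log(rng.uniform(60, 180, n)),
        })
        d, _ = behavior._standardize_distances(rows)
        X, _ = build_design(d, behavior.REVISIT_TERMS)
        beta = np.array([0.5, 0.0, beta_dv, 0.0, 0.3, 0.0, 0.0])
        lam = np.exp(X @ beta)
        rows["n_visits"] = rvs_zt_poisson(lam, rng)
        return rows

    def test_negative_village_effect_recovered(self, rng):
        rows = self._simulate_rows(rng, beta_dv=-0.5)
        fit, r2 = behavior.fit_revisitation(rows)
        j = fit.term_names.index("d_village")
        assert fit.coef[j] < 0
        assert abs(fit.coef[j] + 0.5) < 2 * fit.se[j]
        assert 0.0 <= r2 <= 1.0

    def test_null_simulation_slopes_cover_zero(self, rng):
        rows = self._simulate_rows(rng, beta_dv=0.0)
        fit, _ = behavior.fit_revisitation(rows)
        j = fit.term_names.index("d_village")
        assert abs(fit.coef[j]) < 2 * fit.se[j]

    def test_too_few_rows_rejected(self, rng):
        rows = self._simulate_rows(rng, 0.0).head(10)
        with pytest.raises(ValueError):
            behavior.fit_revisitation(rows)


def make_phase_rows(rng, n=600, p=(0.08, 0.12, 0.17)):
    season = rng.choice([NHS, HS_NONHUNTING, HS_HUNTING_DAY], n)
    pmap = dict(zip([NHS, HS_NONHUNTING, HS_HUNTING_DAY], p))
    rows = pd.DataFrame({
        "animal_id": rng.choice([f"a{i}" for i in range(6)], n),
        "study_site": "area0",
        "date": [date(2021, 1, 1)] * n,
        "season3": season,
        "veg": rng.integers(0, 2, n),
        "d_village_m": rng.exponential(800.0, n),
        "d_road_m": rng.exponential(500.0, n),
        "relocated": [int(rng.uniform() < pmap[s]) for s in season],
    })
    rows["distance_m"] = np.where(rows["relocated"] == 1,
                                  100 + rng.lognormal(np.log(130), 0.7, n), np.nan)
    return rows


class TestRelocationDataset:
    def test_distance_km_and_binary_coding(self, rng):
        rows = make_phase_rows(rng, n=50)
        rows.loc[0, ["relocated", "distance_m"]] = [1, 250.0]
        out = behavior.build_relocation_dataset(rows)
        assert out.loc[0, "distance_km"] == pytest.approx(0.25)
        assert set(out["relocated"]) <= {0, 1}

    def test_season_dummies_reference_nhs(self, rng):
        out = behavior.build_relocation_dataset(make_phase_rows(rng, n=100))
        nhs = out[out["season3"] == NHS]
        assert (nhs["season_HS_nonhunting"] == 0).all()
        assert (nhs["season_HS_hunting_day"] == 0).all()


class TestRelocationFit:
    def test_per_season_probabilities_recovered(self):
        rng = np.random.default_rng(77)
        rows = make_phase_rows(rng, n=8000)
        data = behavior.build_relocation_dataset(rows)
        fit = behavior.fit_relocation(data)
        pred = behavior.predicted_relocation_probabilities(fit, data)
        for season, truth in ((NHS, 0.08), (HS_NONHUNTING, 0.12),
                              (HS_HUNTING_DAY, 0.17)):
            assert abs(pred[season]["p"] - truth) < 0.03

    def test_reference_category_invariance(self):
        # recoding the 3-level season with a different reference category
        # leaves the per-season predicted probabilities unchanged
        rng = np.random.default_rng(78)
        rows = make_phase_rows(rng, n=1500)
        data = behavior.build_relocation_dataset(rows)
        fit = behavior.fit_relocation(data)
        pred = behavior.predicted_relocation_probabilities(fit, data)

        alt, _ = behavior._standardize_distances(data)
        alt["season_NHS"] = (alt["season3"] == NHS).astype(int)
        alt_terms = ["veg", "d_village", "d_road", "season_NHS",
                     "season_HS_nonhunting", "veg:d_village", "veg:d_road"]
        X, names = build_design(alt, alt_terms)
        fit2 = fit_glmm(X, alt["relocated"].to_numpy(), "binomial",
                        site=alt["study_site"].to_numpy(),
                        animal=alt["animal_id"].to_numpy(), term_names=names)
        # predict at veg=1, distances at mean (0 after standardization)
        for season, dummies in ((NHS, (1, 0)), (HS_NONHUNTING, (0, 1)),
                                (HS_HUNTING_DAY, (0, 0))):
            x = np.array([1.0, 1.0, 0.0, 0.0, dummies[0], dummies[1], 0.0, 0.0])
            p2, *_ = predict_response(fit2, x)
            assert p2 == pytest.approx(pred[season]["p"], abs=1e-3)

    def test_distance_model_recovers_median_scale(self):
        # distances ~ lognormal with median 237 m and small log-sd: the
        # gamma log-link intercept estimates the mean, which is then close
        # to log(0.237) on the km scale
        rng = np.random.default_rng(79)
        rows = make_phase_rows(rng, n=4000, p=(0.3, 0.3, 0.3))
        rows["distance_m"] = np.where(
            rows["relocated"] == 1, rng.lognormal(np.log(237.0), 0.1, len(rows)),
            np.nan)
        data = behavior.build_relocation_dataset(rows)
        fit = behavior.fit_relocation_distance(data)
        j = fit.term_names.index("Intercept")
        assert abs(fit.coef[j] - np.log(0.237)) < 2 * fit.se[j] + 0.01

    def test_no_relocations_flagged(self, rng):
        rows = make_phase_rows(rng, n=100, p=(0.0, 0.0, 0.0))
        data = behavior.build_relocation_dataset(rows)
        fit = behavior.fit_relocation(data)
        assert fit.penalized
        with pytest.raises(ValueError):
            behavior.fit_relocation_distance(data)
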