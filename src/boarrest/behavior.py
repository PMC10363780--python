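"""Behavioral models: revisitation intensity, relocation probability, and
relocation distance.

Revisitation: the number of visits to each resting site (>= 1 by
construction, so zero-truncated Poisson) as a function of vegetation cover
and distances to villages and roads, with the log survey length as a control
and animal-within-study-site random intercepts; one model per 2-level
season.  Relocation: a binomial model of whether a phase contained a
relocation, with the 3-level hunting-season factor, and a gamma (log link)
model of the distance moved (km) on phases that did relocate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import glmm
from .landscape import HS_HUNTING_DAY, HS_NONHUNTING, NHS

log = logging.getLogger("boarrest")

REVISIT_TERMS = ["veg", "d_village", "d_road", "log_survey_length",
                 "veg:d_village", "veg:d_road"]
RELOC_TERMS = ["veg", "d_village", "d_road", "season_HS_nonhunting",
               "season_HS_hunting_day", "veg:d_village", "veg:d_road"]


def build_revisit_dataset(sites_df: pd.DataFrame, records: dict,
                          season2: str) -> pd.DataFrame:
    """One row per resting site visited >= 1 time in the season.

    ``records``: animal_id -> AnimalRecord supplying the survey length.
    Distances are converted to km (standardized at fit time).
    """
    col = f"n_visits_{season2}"
    sub = sites_df[sites_df[col] > 0].copy()
    lengths = {}
    for aid in sub["animal_id"].unique():
        if aid not in records:
            raise ValueError(f"missing survey length for animal {aid}")
        lengths[aid] = records[aid].survey_length_days
    sub["n_visits"] = sub[col]
    sub["log_survey_length"] = np.log([lengths[a] for a in sub["animal_id"]])
    sub["d_village"] = sub["d_village_m"] / 1000.0
    sub["d_road"] = sub["d_road_m"] / 1000.0
    if "study_site" not in sub.columns:
        sub["study_site"] = "area0"
    return sub.reset_index(drop=True)


def fit_revisitation(rows: pd.DataFrame, terms=REVISIT_TERMS,
                     min_rows: int = 30) -> tuple:
    """Zero-truncated Poisson GLMM of visit counts; returns (fit, marginal R^2)."""
    if len(rows) < min_rows:
        raise ValueError(f"too few sites to fit revisitation model ({len(rows)})")
    d, _ = _standardize_distances(rows)
    X, names = glmm.build_design(d, terms)
    fit = glmm.fit_glmm(X, d["n_visits"].to_numpy(), "zt_poisson",
                        site=d["study_site"].to_numpy(),
                        animal=d["animal_id"].to_numpy(), term_names=names)
    return fit, glmm.marginal_r2(fit)


def build_relocation_dataset(phases_df: pd.DataFrame) -> pd.DataFrame:
    """One row per inactive phase with the initial resting site's covariates.

    ``phases_df`` needs columns animal_id, study_site, date, season3,
    veg, d_village_m, d_road_m, relocated (0/1) and, for relocated phases,
    distance_m of the first event.  Emits distance_km and season dummies
    (reference NHS).
    """
    d = phases_df.copy()
    d["d_village"] = d["d_village_m"] / 1000.0
    d["d_road"] = d["d_road_m"] / 1000.0
    d["season_HS_nonhunting"] = (d["season3"] == HS_NONHUNTING).astype(int)
    d["season_HS_hunting_day"] = (d["season3"] == HS_HUNTING_DAY).astype(int)
    d["relocated"] = d["relocated"].astype(int)
    if "distance_m" in d.columns:
        d["distance_km"] = d["distance_m"] / 1000.0
    if "study_site" not in d.columns:
        d["study_site"] = "area0"
    return d.reset_index(drop=True)


def fit_relocation(rows: pd.DataFrame, terms=RELOC_TERMS) -> glmm.GlmmFit:
    """Binomial GLMM of the probability that a phase contains a relocation."""
    if rows["season3"].nunique() < 2:
        log.warning("only one season category present in relocation data")
    d, _ = _standardize_distances(rows)
    X, names = glmm.build_design(d, terms)
    return glmm.fit_glmm(X, d["relocated"].to_numpy(), "binomial",
                         site=d["study_site"].to_numpy(),
                         animal=d["animal_id"].to_numpy(), term_names=names)


def fit_relocation_distance(rows: pd.DataFrame, terms=RELOC_TERMS) -> glmm.GlmmFit:
    """Gamma (log link) GLMM of relocation distance (km), relocated rows only."""
    moved = rows[rows["relocated"] == 1].copy()
    if moved.empty:
        raise ValueError("no relocation events to model distances from")
    d, _ = _standardize_distances(moved)
    X, names = glmm.build_design(d, terms)
    return glmm.fit_glmm(X, d["distance_km"].to_numpy(), "gamma_log",
                         site=d["study_site"].to_numpy(),
                         animal=d["animal_id"].to_numpy(), term_names=names)


def predicted_relocation_probabilities(fit: glmm.GlmmFit, rows: pd.DataFrame,
                                       terms=RELOC_TERMS, veg: int = 1) -> dict:
    """Per-season predicted probability (with CI) at a reference profile.

    Reference: vegetation as given (default inside dense vegetation) and the
    distance covariates at their data means — after standardization, 0.
    """
    d, _ = _standardize_distances(rows)
    base = {t: 0.0 for t in terms}
    out = {}
    for season, dummies in ((NHS, (0, 0)), (HS_NONHUNTING, (1, 0)),
                            (HS_HUNTING_DAY, (0, 1))):
        prof = dict(base)
        prof["veg"] = veg
        prof["season_HS_nonhunting"], prof["season_HS_hunting_day"] = dummies
        row = pd.DataFrame([prof])
        X, names = glmm.build_design(row, terms)
        # respect columns dropped from a rank-deficient design
        keep = [names.index(t) for t in fit.term_names]
        p, lo, hi = glmm.predict_response(fit, X[0][keep])
        out[season] = {"p": p, "lo": lo, "hi": hi}
    return out


def _standardize_distances(df: pd.DataFrame, cols=("d_village", "d_road")):
    scale = {}
    d = df.copy()
    for c in cols:
        mu, sd = float(d[c].mean()), float(d[c].std())
        sd = sd if sd > 0 else 1.0
        d[c] = (d[c] - mu) / sd
        scale[c] = (mu, sd)
    return d, scale
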