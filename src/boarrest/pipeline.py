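"""End-to-end orchestration: sensor series -> phases -> relocations ->
resting sites -> covariates -> fitted models -> summary.

`analyze_study` runs every stage on a study (simulated or loaded), returning
a bundle of stage tables, fitted models and a summary whose statistics are
all recomputable from the stage tables.  `validate_against_truth` scores the
recovered phases, events and site partition against a simulation's truth
tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, glmm, sites as sites_mod
from .landscape import NHS
from .relocation import RelocationParams, detect_relocations, events_frame
from .segmentation import (SegmentationParams, extract_inactive_phases,
                           inactive_time_fraction, phase_timing_stats, sun_times)
from .selection import (AVAILABLE_PER_USED, CvConfig, boyce_cv,
                        build_rsf_dataset, fit_rsf, home_range_90kde,
                        standardize)

log = logging.getLogger("boarrest")


@dataclass
class StudyContext:
    """Minimal study-location context needed by the analysis."""

    latitude: float
    longitude: float
    tz: str = "UTC"


@dataclass
class Study:
    """A loaded (non-simulated) study: same interface as SimulatedStudy."""

    config: StudyContext
    landscape: object
    calendar: object
    animals: dict      # id -> (ActSeries, GpsTrack, AnimalRecord, None)


@dataclass
class PipelineOptions:
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    reloc_params: RelocationParams = field(default_factory=RelocationParams)
    cluster_cutoff_m: float = 50.0
    n_available_per_used: int = AVAILABLE_PER_USED
    cv: CvConfig = field(default_factory=CvConfig)
    run_selection: bool = True       # home ranges + RSF + SR + CV
    run_behavior_models: bool = True  # revisitation + relocation GLMMs
    min_revisit_rows: int = 30
    rsf_seed: int = 0


def analyze_study(study, opts: PipelineOptions = None) -> dict:
    """Run the full analysis on a (simulated) study.

    ``study`` provides: ``animals`` mapping id -> (ActSeries, GpsTrack,
    AnimalRecord, truth-or-None), ``landscape``, ``calendar`` and ``config``
    (latitude/longitude/tz).  Returns a dict bundle; see the summary key for
    the headline statistics.
    """
    opts = opts or PipelineOptions()
    cfg = study.config
    cal = study.calendar
    scape = study.landscape

    phases_by_animal, events, daily_locs = {}, [], []
    sun_cache = {}
    for aid, (act, gps, rec, _truth) in study.animals.items():
        phases = extract_inactive_phases(act, cfg.latitude, cfg.longitude,
                                         tz=cfg.tz, params=opts.seg_params)
        phases_by_animal[aid] = phases
        for ph in phases:
            sun_cache.setdefault(ph.date, sun_times(cfg.latitude, cfg.longitude, ph.date))
            evs = detect_relocations(ph, act, gps, opts.reloc_params,
                                     opts.seg_params,
                                     season_label=cal.season_label(ph.date))
            events.extend(evs)
            loc = sites_mod.daily_resting_location(ph, gps, evs)
            if loc is not None:
                daily_locs.append(loc)

    all_phases = [p for ps in phases_by_animal.values() for p in ps]
    timing = phase_timing_stats(all_phases, sun_cache) if all_phases else {}
    results_timing = timing

    # ----- sites ----------------------------------------------------------
    sites_frames = []
    for aid in study.animals:
        locs = [l for l in daily_locs if l.animal_id == aid]
        if not locs:
            continue
        labels = sites_mod.cluster_resting_sites(locs, opts.cluster_cutoff_m)
        sf = sites_mod.build_sites(locs, labels, cal.season2, scape)
        sf["study_site"] = study.animals[aid][2].site_id
        sites_frames.append(sf)
    sites_df = (pd.concat(sites_frames, ignore_index=True)
                if sites_frames else pd.DataFrame())

    # ----- relocation dataset --------------------------------------------
    ev_by_key = {}
    for ev in events:
        ev_by_key.setdefault((ev.animal_id, ev.date), []).append(ev)
    loc_by_key = {(l.animal_id, l.date): l for l in daily_locs}
    rows = []
    for aid, phases in phases_by_animal.items():
        rec = study.animals[aid][2]
        for ph in phases:
            loc = loc_by_key.get((aid, ph.date))
            if loc is None:
                continue
            cov = scape.covariates(loc.x, loc.y)
            evs = sorted(ev_by_key.get((aid, ph.date), []),
                         key=lambda e: e.event_time)
            rows.append(dict(
                animal_id=aid, study_site=rec.site_id, date=ph.date,
                season3=cal.season_label(ph.date),
                veg=int(np.atleast_1d(cov["veg"])[0]),
                d_village_m=float(np.atleast_1d(cov["d_village_m"])[0]),
                d_road_m=float(np.atleast_1d(cov["d_road_m"])[0]),
                relocated=int(bool(evs)),
                distance_m=evs[0].distance_m if evs else np.nan))
    phase_rows = pd.DataFrame(rows)

    results = {
        "phases_by_animal": phases_by_animal,
        "timing": results_timing,
        "events": events,
        "events_df": events_frame(events),
        "daily_locations": daily_locs,
        "sites_df": sites_df,
        "phase_rows": phase_rows,
    }

    # ----- behavioral models ---------------------------------------------
    if opts.run_behavior_models and not phase_rows.empty:
        reloc_data = behavior.build_relocation_dataset(phase_rows)
        reloc_fit = behavior.fit_relocation(reloc_data)
        results["relocation_fit"] = reloc_fit
        results["relocation_r2"] = glmm.marginal_r2(reloc_fit)
        results["predicted_p_reloc"] = behavior.predicted_relocation_probabilities(
            reloc_fit, reloc_data)
        if reloc_data["relocated"].sum() >= 10:
            dist_fit = behavior.fit_relocation_distance(reloc_data)
            results["distance_fit"] = dist_fit

        records = {aid: t[2] for aid, t in study.animals.items()}
        results["revisit_fits"] = {}
        for season in ("NHS", "HS"):
            try:
                rv = behavior.build_revisit_dataset(sites_df, records, season)
                fit, r2 = behavior.fit_revisitation(rv, min_rows=opts.min_revisit_rows)
                results["revisit_fits"][season] = {"fit": fit, "r2": r2, "n": len(rv)}
            except ValueError as exc:
                log.warning("revisitation model (%s) skipped: %s", season, exc)

    # ----- selection analysis --------------------------------------------
    if opts.run_selection and not sites_df.empty:
        rng = np.random.default_rng(opts.rsf_seed)
        home_ranges = {}
        for aid, (act, gps, rec, _t) in study.animals.items():
            in_phase = np.zeros(len(gps.times), dtype=bool)
            t = gps.times.astype("datetime64[s]")
            for ph in phases_by_animal[aid]:
                in_phase |= ((t >= np.datetime64(ph.start, "s"))
                             & (t < np.datetime64(ph.end, "s")))
            try:
                home_ranges[aid] = home_range_90kde(gps.x[~in_phase], gps.y[~in_phase],
                                                   animal_id=aid)
            except ValueError as exc:
                log.warning("home range for %s skipped: %s", aid, exc)
        results["home_ranges"] = home_ranges
        results["rsf"] = {}
        for season in ("NHS", "HS"):
            ds = build_rsf_dataset(sites_df[sites_df["animal_id"].isin(home_ranges)],
                                   home_ranges, scape, season, rng,
                                   n_per_used=opts.n_available_per_used)
            if ds.empty or ds["used"].sum() < 5:
                log.warning("RSF (%s) skipped: too few used sites", season)
                continue
            ds_std, scale = standardize(ds)
            fit = fit_rsf(ds_std)
            cv_res = boyce_cv(ds_std, opts.cv)
            n_used = int(ds["used"].sum())
            results["rsf"][season] = {"fit": fit, "cv": cv_res, "scale": scale,
                                      "n_used": n_used,
                                      "n_available": len(ds) - n_used,
                                      "dataset": ds_std}

    results["summary"] = summarize(results, all_phases, cal)
    return results


def summarize(results, all_phases, calendar) -> dict:
    """Headline statistics, all recomputable from the stage tables."""
    s = {}
    if all_phases:
        s["inactive_time_fraction"] = inactive_time_fraction(all_phases)
        s["phase_timing"] = results.get("timing", {})
    phase_rows = results.get("phase_rows", pd.DataFrame())
    if not phase_rows.empty:
        per = phase_rows.groupby("season3")["relocated"].agg(["mean", "sum", "count"])
        s["p_reloc_observed"] = {k: float(v) for k, v in per["mean"].items()}
        moved = phase_rows[phase_rows["relocated"] == 1]
        long_m = moved[moved["distance_m"] > 500.0]
        s["n_relocations"] = int(len(moved))
        s["n_long_relocations"] = int(len(long_m))
        s["n_long_relocations_HS"] = int((long_m["season3"] != NHS).sum())
    sites_df = results.get("sites_df", pd.DataFrame())
    if not sites_df.empty:
        s["site_stats"] = sites_mod.count_visits(sites_df)
    if "predicted_p_reloc" in results:
        s["p_reloc_model"] = {k: v["p"] for k, v in results["predicted_p_reloc"].items()}
    if "revisit_fits" in results:
        s["revisit_r2"] = {k: v["r2"] for k, v in results["revisit_fits"].items()}
    if results.get("rsf"):
        s["rsf_cv"] = {k: v["cv"] for k, v in results["rsf"].items()}
    return s


# ---------------------------------------------------------------------------
# Truth validation (simulated studies)
# ---------------------------------------------------------------------------

def validate_against_truth(study, results) -> dict:
    """Score recovered phases, relocations and site labels against truth."""
    out = {}
    truth = study.truth_phases
    tol = np.timedelta64(5 * 60, "s")

    matched = 0
    total = 0
    detected = {(p.animal_id, p.date): p
                for ps in results["phases_by_animal"].values() for p in ps}
    for _, r in truth.iterrows():
        total += 1
        p = detected.get((r["animal_id"], r["date"]))
        if p is None:
            continue
        ds = abs(np.datetime64(p.start, "s") - np.datetime64(r["start"], "s"))
        de = abs(np.datetime64(p.end, "s") - np.datetime64(r["end"], "s"))
        if ds <= tol and de <= tol:
            matched += 1
    out["phase_recovery_rate"] = matched / total if total else np.nan
    out["n_days"] = total

    # relocation detector performance
    ev_keys = {(e.animal_id, e.date) for e in results["events"]}
    true_pos = truth[truth["relocated"]]
    no_reloc = truth[~truth["relocated"]]
    out["reloc_recall"] = (
        float(np.mean([(r["animal_id"], r["date"]) in ev_keys
                       for _, r in true_pos.iterrows()])) if len(true_pos) else np.nan)
    out["reloc_fpr"] = (
        float(np.mean([(r["animal_id"], r["date"]) in ev_keys
                       for _, r in no_reloc.iterrows()])) if len(no_reloc) else np.nan)
    out["n_true_relocations"] = int(len(true_pos))
    out["n_phases"] = int(len(truth))

    # clustering: adjusted Rand index against the generator's site labels
    from sklearn.metrics import adjusted_rand_score
    aris = []
    truth_by_key = {(r["animal_id"], r["date"]): r["site_id"]
                    for _, r in truth.iterrows()}
    for aid in study.animals:
        locs = [l for l in results["daily_locations"] if l.animal_id == aid]
        if len(locs) < 2:
            continue
        labels = sites_mod.cluster_resting_sites(
            locs, 50.0)
        true_labels = [truth_by_key.get((aid, l.date), -1) for l in locs]
        aris.append(adjusted_rand_score(true_labels, labels))
    out["site_ari"] = float(np.mean(aris)) if aris else np.nan
    return out


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def write_report(results, out_dir, seeds=None) -> None:
    """Write stage CSVs, model coefficient tables and the summary JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phases = [dict(animal_id=p.animal_id, date=p.date, start=p.start, end=p.end,
                   epoch_count=p.epoch_count, low_confidence=p.low_confidence)
              for ps in results["phases_by_animal"].values() for p in ps]
    pd.DataFrame(phases).to_csv(out / "phases.csv", index=False)
    results["events_df"].to_csv(out / "relocations.csv", index=False)
    sites_df = results.get("sites_df", pd.DataFrame())
    if not sites_df.empty:
        sites_df.drop(columns=["member_dates"]).to_csv(out / "sites.csv", index=False)
    if "phase_rows" in results and not results["phase_rows"].empty:
        results["phase_rows"].to_csv(out / "phase_rows.csv", index=False)
    for name in ("relocation_fit", "distance_fit"):
        if name in results:
            results[name].summary_frame().to_csv(out / f"{name}.csv", index=False)
    for season, d in results.get("revisit_fits", {}).items():
        d["fit"].summary_frame().to_csv(out / f"revisit_fit_{season}.csv", index=False)
    for season, d in results.get("rsf", {}).items():
        d["fit"].summary_frame().to_csv(out / f"rsf_fit_{season}.csv", index=False)
    summary = dict(results.get("summary", {}))
    if seeds is not None:
        summary["seeds"] = seeds
    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    return obj
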