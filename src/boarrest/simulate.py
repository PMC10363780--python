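"""Synthetic landscapes and ground-truthed collar data.

The generator emulates the statistical structure the analysis assumes for a
nocturnal, diurnally resting ungulate in a rural mosaic landscape:

* a landscape of building clusters (villages), a sparse high-traffic road
  network, and dense-vegetation patches covering a configurable fraction;
* a 5-min activity series with low values through one consolidated diurnal
  inactive phase (anchored to sunset tightly, to sunrise loosely) and high
  values at night, plus short no-displacement activity bouts within rest;
* a 30-min GPS track that jitters around the day's true resting site during
  the phase and follows a correlated (Ornstein-Uhlenbeck) walk around the
  home centre at night;
* a per-animal pool of resting sites drawn from the landscape with
  configurable selection coefficients, revisited each dawn with log-odds
  increasing as the distance to the nearest village decreases;
* rare within-phase relocations (> 100 m by construction), more probable on
  hunting days of the open season, emitted jointly as an activity bout and a
  displacement of the resting position.

Every stochastic quantity is drawn from a single ``numpy`` Generator, so a
seed fixes the whole study.  Truth tables record the simulated phase bounds,
site identities, relocation events and selection coefficients, giving every
downstream stage an exact oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date as date_t, datetime, time as time_t, timedelta

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, box
from shapely.ops import unary_union

from .data_io import ActSeries, AnimalRecord, GpsTrack
from .landscape import (HS_HUNTING_DAY, HS_NONHUNTING, NHS, HuntingCalendar,
                        Landscape)
from .segmentation import EPOCH_MINUTES, sun_times

log = logging.getLogger("boarrest")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class LandscapeConfig:
    extent_m: float = 8000.0
    n_villages: int = 3
    buildings_per_village: int = 30
    building_size_m: tuple = (15.0, 10.0)
    village_spread_m: float = 120.0
    n_roads: int = 3
    vegetation_fraction: float = 0.4     # target cover, realized within +-5 pp
    veg_patch_radius_m: tuple = (150.0, 400.0)

    def __post_init__(self):
        if self.vegetation_fraction > 0.9:
            raise ValueError("vegetation coverage above 0.9 is infeasible")


@dataclass
class ActivityConfig:
    act_rest_mean: float = 10.0
    act_rest_sd: float = 8.0
    act_active_mean: float = 120.0
    act_active_sd: float = 40.0
    inactive_fraction: float = 0.585     # target share of the 24-h day at rest
    phase_end_sd_min: float = 45.0       # sunset anchoring (tight)
    phase_start_sd_min: float = 90.0     # sunrise anchoring (loose)
    short_bout_rate: float = 2.0         # Poisson mean per phase
    bout_minutes: tuple = (5, 15)        # no-displacement bouts inside rest
    bout_min_act: float = 45.0           # bouts are sustained supra-threshold activity


@dataclass
class SiteConfig:
    #: pool large enough that roughly half the used sites are one-offs over a
    #: ~4-month survey, the rest revisited (concentrated near villages);
    #: separation well above the 50 m clustering cut but far from the packing
    #: limit of the home disk, so the selection weighting is not flattened
    pool_size: int = 100
    min_separation_m: float = 100.0
    home_radius_m: float = 1500.0
    revisit_village_coef: float = 1.0    # log-odds of choice per km closer to village
    gps_noise_sd_m: float = 15.0


@dataclass
class RelocationConfig:
    p_reloc: dict = field(default_factory=lambda: {
        NHS: 0.08, HS_NONHUNTING: 0.12, HS_HUNTING_DAY: 0.17})
    base_distance_m: float = 100.0       # every true relocation exceeds this
    log_extra_mu: float = math.log(130.0)
    log_extra_sd: float = 0.7
    season_distance_multiplier: dict = field(default_factory=lambda: {
        NHS: 1.0, HS_NONHUNTING: 1.2, HS_HUNTING_DAY: 1.7})
    bout_minutes: int = 30               # activity bout emitted at the move
    edge_margin_minutes: int = 120       # keep events away from phase bounds


@dataclass
class SelectionConfig:
    """True resource-selection coefficients for the site pool (distances in km)."""
    beta_veg: float = 1.3
    beta_d_road: float = 0.0
    beta_d_village: float = 0.0


@dataclass
class SimulationConfig:
    seed: int = 0
    n_animals: int = 5
    n_study_sites: int = 2
    survey_length_days: int = 120
    survey_length_sd_days: float = 0.0   # per-animal jitter; 0 = all equal
    start_date: date_t = date_t(2021, 3, 1)
    latitude: float = 43.8
    longitude: float = 3.9
    tz: str = "UTC"
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    activity: ActivityConfig = field(default_factory=ActivityConfig)
    sites: SiteConfig = field(default_factory=SiteConfig)
    relocation: RelocationConfig = field(default_factory=RelocationConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    bank_holidays: tuple = ()

    def __post_init__(self):
        for v in self.relocation.p_reloc.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("relocation probabilities must be in [0, 1]")
        for v in (self.activity.act_rest_mean, self.activity.act_active_mean):
            if not 0 <= v <= 255:
                raise ValueError("activity means must be within [0, 255]")

    def calendar(self) -> HuntingCalendar:
        years = range(self.start_date.year - 1,
                      self.start_date.year + self.survey_length_days // 365 + 1)
        return HuntingCalendar.default_for_years(years, self.bank_holidays)


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def simulate_landscape(config: SimulationConfig, rng) -> dict:
    """Raw vector layers (buildings, roads with categories, vegetation)."""
    lc = config.landscape
    E = lc.extent_m

    centers = []
    for _ in range(2000):
        if len(centers) == lc.n_villages:
            break
        c = rng.uniform(0.15 * E, 0.85 * E, 2)
        if all(np.hypot(*(c - o)) > 0.25 * E for o in centers):
            centers.append(c)
    buildings = []
    w, h = lc.building_size_m
    for c in centers:
        for _ in range(lc.buildings_per_village):
            bx, by = c + rng.normal(0, lc.village_spread_m, 2)
            buildings.append(box(bx - w / 2, by - h / 2, bx + w / 2, by + h / 2))

    cats = ["secondary", "primary", "tertiary", "trunk", "motorway"]
    roads = []
    for i in range(lc.n_roads):
        # a road crossing the extent, passing near a village when possible
        via = centers[i % len(centers)] if centers else rng.uniform(0, E, 2)
        ang = rng.uniform(0, np.pi)
        d = np.array([np.cos(ang), np.sin(ang)]) * 2 * E
        roads.append((LineString([tuple(via - d), tuple(via + d)]).intersection(
            box(0, 0, E, E)), cats[i % len(cats)]))
    # low-traffic roads that the filter must drop
    roads.append((LineString([(0, 0.1 * E), (E, 0.12 * E)]), "residential"))
    roads.append((LineString([(0.1 * E, 0), (0.12 * E, E)]), "track"))
    roads = [(g, c) for g, c in roads if not g.is_empty and g.geom_type == "LineString"]

    vegetation = []
    if lc.vegetation_fraction > 0:
        area_target = lc.vegetation_fraction * E * E
        union = None
        for _ in range(5000):
            r = rng.uniform(*lc.veg_patch_radius_m)
            p = Point(rng.uniform(0, E), rng.uniform(0, E)).buffer(r, quad_segs=8)
            p = p.intersection(box(0, 0, E, E))
            vegetation.append(p)
            union = p if union is None else unary_union([union, p])
            if union.area >= area_target:
                break
    return {"buildings": buildings, "roads": roads, "vegetation": vegetation,
            "extent": (0.0, 0.0, E, E)}


# ---------------------------------------------------------------------------
# Animal simulation
# ---------------------------------------------------------------------------

def _snap(dt: datetime, minutes=EPOCH_MINUTES) -> datetime:
    s = int(round(dt.timestamp() / (minutes * 60))) * minutes * 60
    return datetime.utcfromtimestamp(s)


def _site_pool(config, landscape: Landscape, center, rng):
    sc, sel = config.sites, config.selection
    n_cand = 4000
    ang = rng.uniform(0, 2 * np.pi, n_cand)
    rad = sc.home_radius_m * np.sqrt(rng.uniform(0, 1, n_cand))
    xs = center[0] + rad * np.cos(ang)
    ys = center[1] + rad * np.sin(ang)
    cov = landscape.covariates(xs, ys)
    eta = (sel.beta_veg * np.asarray(cov["veg"], dtype=float)
           + sel.beta_d_road * np.asarray(cov["d_road_m"]) / 1000.0
           + sel.beta_d_village * np.asarray(cov["d_village_m"]) / 1000.0)
    w = np.exp(eta - eta.max())
    chosen = []
    order = rng.choice(n_cand, size=n_cand, replace=False, p=w / w.sum())
    for idx in order:
        if len(chosen) == sc.pool_size:
            break
        if all(np.hypot(xs[idx] - xs[j], ys[idx] - ys[j]) >= sc.min_separation_m
               for j in chosen):
            chosen.append(idx)
    if len(chosen) < sc.pool_size:
        log.warning("site pool truncated to %d sites", len(chosen))
    pool = pd.DataFrame({
        "site_id": np.arange(len(chosen)),
        "x": xs[chosen], "y": ys[chosen],
        "veg": np.asarray(cov["veg"])[chosen],
        "d_village_m": np.asarray(cov["d_village_m"])[chosen],
        "d_road_m": np.asarray(cov["d_road_m"])[chosen],
    })
    return pool


def simulate_animal(config: SimulationConfig, landscape: Landscape,
                    calendar: HuntingCalendar, animal_id: str, study_site: str,
                    rng, survey_days=None):
    """Simulate one animal: (ActSeries, GpsTrack, AnimalRecord, truth dict)."""
    ac, sc, rc = config.activity, config.sites, config.relocation
    days = int(survey_days or config.survey_length_days)

    E = config.landscape.extent_m
    margin = sc.home_radius_m
    center = rng.uniform(margin, E - margin, 2) if E > 2 * margin else np.array([E / 2, E / 2])
    pool = _site_pool(config, landscape, center, rng)
    choice_w = np.exp(-sc.revisit_village_coef * pool["d_village_m"].to_numpy() / 1000.0)
    choice_w = choice_w / choice_w.sum()

    dates = [config.start_date + timedelta(days=i) for i in range(days)]
    suns = {d: sun_times(config.latitude, config.longitude, d) for d in dates}
    daylen_mean = np.mean([(s.sunset_utc - s.sunrise_utc).total_seconds() / 60.0
                           for s in suns.values()])
    # phase start offset from sunrise chosen so the expected phase length
    # matches the target inactive fraction of the 24-h day
    start_mu = daylen_mean - ac.inactive_fraction * 24.0 * 60.0

    phase_rows, bout_windows, reloc_rows = [], [], []
    for d in dates:
        st = suns[d]
        end_off = np.clip(rng.normal(0.0, ac.phase_end_sd_min),
                          -2.5 * ac.phase_end_sd_min, 2.5 * ac.phase_end_sd_min)
        start_off = np.clip(rng.normal(start_mu, ac.phase_start_sd_min),
                            start_mu - 2.5 * ac.phase_start_sd_min,
                            start_mu + 2.5 * ac.phase_start_sd_min)
        start = _snap(st.sunrise_utc + timedelta(minutes=float(start_off)))
        end = _snap(st.sunset_utc + timedelta(minutes=float(end_off)))
        if end <= start + timedelta(hours=4):
            end = start + timedelta(hours=4)

        site_idx = int(rng.choice(len(pool), p=choice_w))
        srow = pool.iloc[site_idx]
        season3 = calendar.season_label(d)

        reloc = None
        usable = (end - start) - 2 * timedelta(minutes=rc.edge_margin_minutes) \
            - timedelta(minutes=rc.bout_minutes)
        if rng.uniform() < rc.p_reloc.get(season3, 0.0) and usable > timedelta(0):
            t_rel = _snap(start + timedelta(minutes=rc.edge_margin_minutes)
                          + rng.uniform() * usable)
            dist = rc.base_distance_m + float(
                rng.lognormal(rc.log_extra_mu, rc.log_extra_sd)
                * rc.season_distance_multiplier.get(season3, 1.0))
            theta = rng.uniform(0, 2 * np.pi)
            nx = srow["x"] + dist * np.cos(theta)
            ny = srow["y"] + dist * np.sin(theta)
            reloc = dict(animal_id=animal_id, date=d, time=t_rel,
                         distance_m=dist, x=nx, y=ny, season3=season3)
            reloc_rows.append(reloc)
            bout_windows.append((t_rel, t_rel + timedelta(minutes=rc.bout_minutes)))

        # Short no-displacement bouts: isolated comfort movements, kept clear
        # of the phase bounds and of each other (>= 2 h apart) so the phase
        # remains one consolidated rest under the smoothing definition.
        day_windows = [bout_windows[-1]] if reloc else []
        spacing = timedelta(minutes=120)
        for _ in range(rng.poisson(ac.short_bout_rate)):
            dur = int(rng.integers(ac.bout_minutes[0] // EPOCH_MINUTES,
                                   ac.bout_minutes[1] // EPOCH_MINUTES + 1)) * EPOCH_MINUTES
            lo = start + timedelta(minutes=rc.edge_margin_minutes)
            hi = end - timedelta(minutes=rc.edge_margin_minutes + dur)
            if hi <= lo:
                continue
            for _try in range(20):
                t0 = _snap(lo + rng.uniform() * (hi - lo))
                t1 = t0 + timedelta(minutes=dur)
                if all(t0 - spacing >= w1 or t1 + spacing <= w0
                       for w0, w1 in day_windows):
                    day_windows.append((t0, t1))
                    bout_windows.append((t0, t1))
                    break

        phase_rows.append(dict(
            animal_id=animal_id, date=d, season3=season3,
            season2=calendar.season2(d), start=start, end=end,
            site_id=int(srow["site_id"]), site_x=float(srow["x"]),
            site_y=float(srow["y"]), relocated=reloc is not None,
            reloc_distance_m=(reloc["distance_m"] if reloc else np.nan)))

    phases = pd.DataFrame(phase_rows)
    relocs = pd.DataFrame(reloc_rows, columns=[
        "animal_id", "date", "time", "distance_m", "x", "y", "season3"])

    survey_start = datetime.combine(dates[0], time_t(0, 0))
    survey_end = datetime.combine(dates[-1] + timedelta(days=1), time_t(0, 0))

    # ----- activity series ------------------------------------------------
    n_epochs = int((survey_end - survey_start).total_seconds() // (EPOCH_MINUTES * 60))
    times = np.array([survey_start + timedelta(minutes=EPOCH_MINUTES * i)
                      for i in range(n_epochs)], dtype="datetime64[s]")
    resting = np.zeros(n_epochs, dtype=bool)
    t0 = np.datetime64(survey_start, "s")
    for r in phase_rows:
        i0 = int((np.datetime64(r["start"], "s") - t0) / np.timedelta64(EPOCH_MINUTES * 60, "s"))
        i1 = int((np.datetime64(r["end"], "s") - t0) / np.timedelta64(EPOCH_MINUTES * 60, "s"))
        resting[max(i0, 0):min(i1, n_epochs)] = True
    bout_mask = np.zeros(n_epochs, dtype=bool)
    for b0, b1 in bout_windows:
        i0 = int((np.datetime64(b0, "s") - t0) / np.timedelta64(EPOCH_MINUTES * 60, "s"))
        i1 = int((np.datetime64(b1, "s") - t0) / np.timedelta64(EPOCH_MINUTES * 60, "s"))
        bout_mask[max(i0, 0):min(i1, n_epochs)] = True
    act = np.where(resting,
                   rng.normal(ac.act_rest_mean, ac.act_rest_sd, n_epochs),
                   rng.normal(ac.act_active_mean, ac.act_active_sd, n_epochs))
    # bouts within rest are sustained activity: every epoch stays above the
    # classification threshold, unlike ordinary nocturnal activity
    act[bout_mask] = np.clip(rng.normal(ac.act_active_mean, ac.act_active_sd,
                                        int(bout_mask.sum())),
                             ac.bout_min_act, None)
    act = np.clip(np.round(act), 0, 255).astype(int)
    act_series = ActSeries(animal_id, times, act)

    # ----- GPS track ------------------------------------------------------
    gps_step = timedelta(minutes=30)
    n_fix = int((survey_end - survey_start) / gps_step)
    fix_times = [survey_start + gps_step * i for i in range(n_fix)]
    by_date = {r["date"]: r for r in phase_rows}
    rel_by_date = {r["date"]: r for r in reloc_rows}
    rho = 0.85
    walk_sd = 600.0
    innov = walk_sd * math.sqrt(1 - rho ** 2)
    commute = timedelta(minutes=60)     # approach/departure window at the bounds
    pos = center + rng.normal(0, walk_sd, 2)
    xs, ys = np.empty(n_fix), np.empty(n_fix)

    def rest_anchor(r, t):
        rel = rel_by_date.get(r["date"])
        if rel is not None and t >= rel["time"]:
            return np.array([rel["x"], rel["y"]])
        return np.array([r["site_x"], r["site_y"]])

    for i, t in enumerate(fix_times):
        r = by_date.get(t.date())
        if r is not None and r["start"] <= t < r["end"]:
            anchor = rest_anchor(r, t)
            p = anchor + rng.normal(0, sc.gps_noise_sd_m, 2)
            pos = anchor
        elif r is not None and t < r["start"] and r["start"] - t <= commute:
            # returning to the chosen site at the end of the night
            anchor = np.array([r["site_x"], r["site_y"]])
            p = anchor + rng.normal(0, 30.0, 2)
            pos = anchor
        elif r is not None and t >= r["end"] and t - r["end"] <= commute:
            # lingering near the site just after rising
            anchor = rest_anchor(r, t)
            p = anchor + rng.normal(0, 30.0, 2)
            pos = anchor
        else:
            pos = center + rho * (pos - center) + rng.normal(0, innov, 2)
            p = pos
        xs[i], ys[i] = p
    gps = GpsTrack(animal_id, np.array(fix_times, dtype="datetime64[s]"), xs, ys)

    record = AnimalRecord(animal_id, study_site, "male",
                          survey_start - timedelta(days=3), survey_start, survey_end)
    truth = {"phases": phases, "relocations": relocs, "site_pool": pool,
             "selection": config.selection}
    return act_series, gps, record, truth


# ---------------------------------------------------------------------------
# Whole-study driver
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    raw_landscape: dict
    landscape: Landscape
    calendar: HuntingCalendar
    animals: dict            # id -> (ActSeries, GpsTrack, AnimalRecord, truth)

    @property
    def truth_phases(self) -> pd.DataFrame:
        return pd.concat([t["phases"] for *_, t in self.animals.values()],
                         ignore_index=True)

    @property
    def truth_relocations(self) -> pd.DataFrame:
        return pd.concat([t["relocations"] for *_, t in self.animals.values()],
                         ignore_index=True)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Simulate landscape plus all animals from the config's seed."""
    rng = np.random.default_rng(config.seed)
    raw = simulate_landscape(config, rng)
    scape = Landscape.from_raw_layers(raw, extent=raw["extent"])
    calendar = config.calendar()
    animals = {}
    lengths = np.full(config.n_animals, float(config.survey_length_days))
    if config.survey_length_sd_days > 0:
        lengths = np.clip(rng.normal(config.survey_length_days,
                                     config.survey_length_sd_days,
                                     config.n_animals), 30, None)
    for i in range(config.n_animals):
        aid = f"boar{i:02d}"
        study_site = f"area{i % config.n_study_sites}"
        animals[aid] = simulate_animal(config, scape, calendar, aid, study_site,
                                       rng, survey_days=int(lengths[i]))
    return SimulatedStudy(config, raw, scape, calendar, animals)
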