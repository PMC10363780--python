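"""Epoch classification and daily inactive-phase extraction.

A nocturnal animal's 24-h cycle is split into one consolidated diurnal
inactive phase and a nocturnal active phase.  Each 5-min epoch is classified
``resting`` (ACT <= 40) or ``active`` (ACT > 40); short bouts of activity
between long resting bouts are smoothed away, and the phase attributed to a
local day is the merged resting run overlapping that day's daylight window.

Sunrise/sunset come from the NOAA solar-position equations (accuracy about a
minute at mid-latitudes), which is what the timing statistics (phase ends
anchored to sunset, starts loosely anchored to sunrise) are measured against.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date as date_t, datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .data_io import ActSeries

log = logging.getLogger("boarrest")

EPOCH_MINUTES = 5


@dataclass
class SegmentationParams:
    """Tunable thresholds of the phase-extraction rule.

    ``act_threshold``: resting iff ACT <= threshold.  ``max_gap_minutes``:
    an active run strictly shorter than this, flanked by resting runs each at
    least ``min_rest_run_minutes`` long, is absorbed into the surrounding
    rest.
    """

    act_threshold: int = 40
    min_rest_run_minutes: int = 120
    max_gap_minutes: int = 60

    def __post_init__(self):
        if not 0 <= self.act_threshold <= 255:
            raise ValueError("act_threshold must be in [0, 255]")
        for v in (self.min_rest_run_minutes, self.max_gap_minutes):
            if v <= 0 or v % EPOCH_MINUTES:
                raise ValueError("durations must be positive multiples of 5 min")


@dataclass
class InactivePhase:
    """One consolidated diurnal rest bout (one per animal-day)."""

    animal_id: str
    date: date_t                 # local calendar day of the daytime spanned
    start: datetime              # UTC
    end: datetime                # UTC
    epoch_count: int
    low_confidence: bool = False

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0


@dataclass
class SunTimes:
    date: date_t
    sunrise_utc: datetime
    sunset_utc: datetime
    latitude: float
    longitude: float


# ---------------------------------------------------------------------------
# Solar geometry (NOAA equations)
# ---------------------------------------------------------------------------

def sun_times(latitude: float, longitude: float, date: date_t) -> SunTimes:
    """Sunrise and sunset (UTC) for a date and location.

    Implements the NOAA solar calculator equations (refraction-corrected
    zenith 90.833 deg).  Valid away from polar latitudes.
    """
    if abs(latitude) >= 66.0:
        raise ValueError("polar latitudes not supported")
    noon_min = _solar_noon_minutes(latitude, longitude, date)
    ha = _hour_angle_deg(latitude, longitude, date)
    midnight = datetime(date.year, date.month, date.day, tzinfo=timezone.utc)
    sunrise = midnight + timedelta(minutes=noon_min - 4 * ha)
    sunset = midnight + timedelta(minutes=noon_min + 4 * ha)
    return SunTimes(date, sunrise.replace(tzinfo=None), sunset.replace(tzinfo=None),
                    latitude, longitude)


def _solar_params(date: date_t):
    # centuries since J2000, evaluated at 12:00 UTC of the date
    jd = date.toordinal() + 1721424.5 + 0.5
    t = (jd - 2451545.0) / 36525.0
    l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    e = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mr = math.radians(m)
    c = (math.sin(mr) * (1.914602 - t * (0.004817 + 0.000014 * t))
         + math.sin(2 * mr) * (0.019993 - 0.000101 * t)
         + math.sin(3 * mr) * 0.000289)
    true_long = l0 + c
    omega = math.radians(125.04 - 1934.136 * t)
    lam = math.radians(true_long - 0.00569 - 0.00478 * math.sin(omega))
    eps0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))
    decl = math.asin(math.sin(eps) * math.sin(lam))
    y = math.tan(eps / 2) ** 2
    l0r = math.radians(l0)
    eot = 4 * math.degrees(
        y * math.sin(2 * l0r) - 2 * e * math.sin(mr)
        + 4 * e * y * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r) - 1.25 * e * e * math.sin(2 * mr))
    return decl, eot


def _solar_noon_minutes(lat, lon, date):
    _, eot = _solar_params(date)
    return 720.0 - 4.0 * lon - eot


def _hour_angle_deg(lat, lon, date):
    decl, _ = _solar_params(date)
    phi = math.radians(lat)
    cos_ha = (math.cos(math.radians(90.833)) / (math.cos(phi) * math.cos(decl))
              - math.tan(phi) * math.tan(decl))
    if abs(cos_ha) > 1.0:
        raise ValueError("polar day/night: sun does not rise/set on this date")
    return math.degrees(math.acos(cos_ha))


# ---------------------------------------------------------------------------
# Classification and run merging
# ---------------------------------------------------------------------------

def classify_epochs(act, params: SegmentationParams = None) -> np.ndarray:
    """Boolean per-epoch labels: True = resting (ACT <= threshold)."""
    thr = (params or SegmentationParams()).act_threshold
    act = act.act if isinstance(act, ActSeries) else np.asarray(act)
    return act <= thr


def _rle(labels: np.ndarray):
    """Run-length encode: list of [value, start_idx, end_idx_exclusive]."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append([bool(labels[start]), start, i])
            start = i
    return runs


def merge_rest_runs(labels, times, params: SegmentationParams):
    """Absorb short active runs flanked by long resting runs.

    Repeatedly absorbs the shortest qualifying active run (strictly shorter
    than ``max_gap_minutes``, both flanking rest runs >=
    ``min_rest_run_minutes``) until a fixed point; shortest-first with
    earliest-start tie-break keeps the result order-independent.  Returns the
    final run list (value, start_idx, end_idx_exclusive).
    """
    times = np.asarray(times, dtype="datetime64[s]")

    def dur_min(run):
        _, s, e = run
        return (times[e - 1] - times[s]) / np.timedelta64(60, "s") + EPOCH_MINUTES

    runs = _rle(np.asarray(labels, dtype=bool))
    while True:
        candidates = [
            (dur_min(runs[i]), runs[i][1], i)
            for i in range(1, len(runs) - 1)
            if not runs[i][0]
            and dur_min(runs[i]) < params.max_gap_minutes
            and runs[i - 1][0] and dur_min(runs[i - 1]) >= params.min_rest_run_minutes
            and runs[i + 1][0] and dur_min(runs[i + 1]) >= params.min_rest_run_minutes
        ]
        if not candidates:
            return runs
        _, _, i = min(candidates)
        merged = [True, runs[i - 1][1], runs[i + 1][2]]
        runs = runs[:i - 1] + [merged] + runs[i + 2:]


# ---------------------------------------------------------------------------
# Phase extraction
# ---------------------------------------------------------------------------

def extract_inactive_phases(act_series: ActSeries, latitude, longitude,
                            tz: str = "UTC",
                            params: SegmentationParams = None) -> list:
    """One inactive phase per local day.

    Resting runs (after bout smoothing) are attributed to the local day whose
    daylight window [sunrise, sunset] they overlap; per day the phase is the
    run with the longest daylight overlap (ties: longer run, then earlier
    start).  A phase starting in the last hours of the night is thereby
    attributed to the following daytime.  Days overlapping a flagged sensor
    gap yield low-confidence phases; days with no resting run overlapping
    daylight yield none (logged).
    """
    params = params or SegmentationParams()
    labels = classify_epochs(act_series, params)
    if not labels.any():
        return []
    runs = [r for r in merge_rest_runs(labels, act_series.times, params) if r[0]]
    times = act_series.times
    run_bounds = [
        (pd.Timestamp(times[s]).to_pydatetime(),
         pd.Timestamp(times[e - 1]).to_pydatetime() + timedelta(minutes=EPOCH_MINUTES),
         e - s)
        for _, s, e in runs
    ]

    local = pd.DatetimeIndex(times, tz="UTC").tz_convert(tz)
    days = sorted(set(local.date))
    gaps = [(pd.Timestamp(a).to_pydatetime(), pd.Timestamp(b).to_pydatetime())
            for a, b in act_series.gaps]

    phases = []
    for day in days:
        try:
            st = sun_times(latitude, longitude, day)
        except ValueError:
            continue
        best = None
        for start, end, n in run_bounds:
            overlap = (min(end, st.sunset_utc) - max(start, st.sunrise_utc)).total_seconds()
            if overlap <= 0:
                continue
            key = (overlap, (end - start).total_seconds(), -start.timestamp())
            if best is None or key > best[0]:
                best = (key, start, end, n)
        if best is None:
            log.info("animal %s day %s: no resting run overlapping daylight",
                     act_series.animal_id, day)
            continue
        _, start, end, n = best
        lowconf = any(gs < end and ge > start for gs, ge in gaps)
        phases.append(InactivePhase(act_series.animal_id, day, start, end, n, lowconf))
    return phases


def phase_timing_stats(phases, sun_lookup, windows=(30, 90)) -> dict:
    """Fractions of phase ends near sunset and phase starts near sunrise.

    ``sun_lookup``: mapping date -> SunTimes (or a callable date -> SunTimes).
    Windows are symmetric (|delta| <= w minutes).  Returns
    ``{"end_within": {w: frac}, "start_within": {w: frac}}``.
    """
    if not phases:
        raise ValueError("no phases supplied")
    get = sun_lookup if callable(sun_lookup) else sun_lookup.__getitem__
    d_end, d_start = [], []
    for ph in phases:
        st = get(ph.date)
        d_end.append(abs((ph.end - st.sunset_utc).total_seconds()) / 60.0)
        d_start.append(abs((ph.start - st.sunrise_utc).total_seconds()) / 60.0)
    d_end, d_start = np.array(d_end), np.array(d_start)
    return {
        "end_within": {w: float((d_end <= w).mean()) for w in windows},
        "start_within": {w: float((d_start <= w).mean()) for w in windows},
    }


def inactive_time_fraction(phases) -> float:
    """Mean fraction of the 24-h day spent in the inactive phase."""
    if not phases:
        raise ValueError("no phases supplied")
    return float(np.mean([p.duration_hours for p in phases]) / 24.0)
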