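"""Within-phase relocation detection from ACT spikes plus GPS displacement.

A relocation is a substantial move of a resting animal during its inactive
phase: a sustained run of supra-threshold activity, with the mean GPS
position before the run more than 100 m (strictly) from the mean position
after it.  Brief activity bouts without displacement (posture shifts,
grooming) produce candidates whose centroid distance stays near zero and are
rejected by the displacement criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

from .segmentation import EPOCH_MINUTES, InactivePhase, SegmentationParams

log = logging.getLogger("boarrest")


@dataclass
class RelocationParams:
    min_displacement_m: float = 100.0    # strict: events require distance > this
    min_active_bout_minutes: int = 10    # supra-threshold run length to qualify
    min_fixes_per_side: int = 2

    def __post_init__(self):
        if self.min_displacement_m <= 0:
            raise ValueError("min_displacement_m must be positive")


@dataclass
class RelocationEvent:
    animal_id: str
    date: object
    event_time: datetime        # start of the triggering activity bout
    pre_centroid: tuple
    post_centroid: tuple
    distance_m: float
    season_label: str = ""


def _active_runs(times, act, threshold, t_start, t_end, min_minutes):
    """Maximal runs of act > threshold strictly inside (t_start, t_end)."""
    t = times.astype("datetime64[s]")
    lo, hi = np.datetime64(t_start, "s"), np.datetime64(t_end, "s")
    mask = (t >= lo) & (t < hi)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    runs, cur = [], None
    for i in idx:
        if act[i] > threshold:
            if cur is None:
                cur = [i, i]
            else:
                cur[1] = i
        elif cur is not None:
            runs.append(cur)
            cur = None
    if cur is not None:
        runs.append(cur)
    out = []
    for s, e in runs:
        start = pd.Timestamp(t[s]).to_pydatetime()
        end = pd.Timestamp(t[e]).to_pydatetime() + pd.Timedelta(minutes=EPOCH_MINUTES)
        if (end - start).total_seconds() / 60.0 >= min_minutes:
            out.append((start, end))
    return out


def detect_relocations(phase: InactivePhase, act_series, gps_track,
                       params: RelocationParams = None,
                       seg_params: SegmentationParams = None,
                       season_label: str = "") -> list:
    """Detect relocation events within one inactive phase.

    Candidates are supra-threshold ACT runs of at least
    ``min_active_bout_minutes``; for each, the centroid of fixes since the
    phase start (or the previous event) is compared with the centroid of
    fixes up to the next candidate (or the phase end).  An event is emitted
    iff the Euclidean distance strictly exceeds ``min_displacement_m``.
    Candidates with too few fixes on either side are skipped (logged).
    """
    params = params or RelocationParams()
    thr = (seg_params or SegmentationParams()).act_threshold
    cands = _active_runs(act_series.times, act_series.act, thr,
                         phase.start, phase.end, params.min_active_bout_minutes)
    gt = gps_track.times.astype("datetime64[s]")
    gx, gy = gps_track.x, gps_track.y

    def centroid(t0, t1):
        m = (gt >= np.datetime64(t0, "s")) & (gt < np.datetime64(t1, "s"))
        if m.sum() < params.min_fixes_per_side:
            return None
        return float(gx[m].mean()), float(gy[m].mean())

    events = []
    seg_start = phase.start
    for i, (c_start, c_end) in enumerate(cands):
        nxt = cands[i + 1][0] if i + 1 < len(cands) else phase.end
        pre = centroid(seg_start, c_start)
        post = centroid(c_end, nxt)
        if pre is None or post is None:
            log.info("animal %s %s: candidate at %s skipped (too few fixes)",
                     phase.animal_id, phase.date, c_start)
            continue
        dist = float(np.hypot(post[0] - pre[0], post[1] - pre[1]))
        if dist > params.min_displacement_m:
            events.append(RelocationEvent(phase.animal_id, phase.date, c_start,
                                          pre, post, dist, season_label))
            seg_start = c_end
    return events


def relocation_summary(events, phases, season_of=None,
                       distance_split_m: float = 500.0) -> pd.DataFrame:
    """Per-season share of phases with >= 1 event, with distances
    partitioned at ``distance_split_m`` for reporting.

    ``season_of``: callable date -> season label; defaults to the events' own
    labels (phases then need ``season`` attributes or a label of "").
    """
    by_key = {}
    for ev in events:
        by_key.setdefault((ev.animal_id, ev.date), []).append(ev)
    rows = {}
    for ph in phases:
        season = season_of(ph.date) if season_of else getattr(ph, "season", "")
        r = rows.setdefault(season, dict(n_phases=0, n_with_event=0,
                                         n_events=0, n_long=0, n_short=0))
        r["n_phases"] += 1
        evs = by_key.get((ph.animal_id, ph.date), [])
        r["n_with_event"] += bool(evs)
        r["n_events"] += len(evs)
        for ev in evs:
            r["n_long" if ev.distance_m > distance_split_m else "n_short"] += 1
    out = pd.DataFrame([{"season": k, **v} for k, v in sorted(rows.items())])
    out["p_reloc"] = out["n_with_event"] / out["n_phases"]
    return out


def events_frame(events) -> pd.DataFrame:
    return pd.DataFrame([{
        "animal_id": ev.animal_id, "date": ev.date, "time": ev.event_time,
        "pre_x": ev.pre_centroid[0], "pre_y": ev.pre_centroid[1],
        "post_x": ev.post_centroid[0], "post_y": ev.post_centroid[1],
        "distance_m": ev.distance_m, "season": ev.season_label,
    } for ev in events], columns=["animal_id", "date", "time", "pre_x", "pre_y",
                                 "post_x", "post_y", "distance_m", "season"])
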