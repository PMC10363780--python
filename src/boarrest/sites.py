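"""Daily resting locations and resting-site clustering.

The resting location of a day is the mean of the phase's GPS fixes acquired
before the first relocation event, so it reflects the site chosen at dawn.
Daily locations of one animal are grouped into resting sites by
agglomerative clustering with average linkage, cutting the dendrogram at
50 m: locations in the same cluster are revisits of the same site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

log = logging.getLogger("boarrest")

CLUSTER_CUTOFF_M = 50.0


@dataclass
class DailyRestingLocation:
    animal_id: str
    date: object
    x: float
    y: float


def daily_resting_location(phase, gps_track, events=()) -> DailyRestingLocation | None:
    """Mean of the phase's fixes before the first relocation event.

    Returns None (logged) when no qualifying fix exists.
    """
    t = gps_track.times.astype("datetime64[s]")
    cutoff = phase.end
    for ev in sorted(events, key=lambda e: e.event_time):
        if ev.date == phase.date:
            cutoff = ev.event_time
            break
    m = (t >= np.datetime64(phase.start, "s")) & (t < np.datetime64(cutoff, "s"))
    if not m.any():
        log.info("animal %s %s: no qualifying fix for resting location",
                 phase.animal_id, phase.date)
        return None
    return DailyRestingLocation(phase.animal_id, phase.date,
                                float(gps_track.x[m].mean()),
                                float(gps_track.y[m].mean()))


def cluster_resting_sites(locations, cutoff_m: float = CLUSTER_CUTOFF_M) -> np.ndarray:
    """Average-linkage agglomerative clustering of one animal's locations.

    The dendrogram is cut so that merges at inter-cluster average distance
    <= ``cutoff_m`` are kept (clusters further apart than the cutoff stay
    separate).  Input order does not affect the partition in generic
    position; SciPy's deterministic merge order breaks exact-distance ties.
    Returns 0-based integer site labels in input order.
    """
    if len(locations) and hasattr(locations[0], "x"):
        xy = np.array([(l.x, l.y) for l in locations])
    else:
        xy = np.asarray(locations, dtype=float).reshape(-1, 2)
    if len(xy) == 0:
        return np.array([], dtype=int)
    if len(xy) == 1:
        return np.zeros(1, dtype=int)
    Z = linkage(pdist(xy), method="average")
    labels = fcluster(Z, t=cutoff_m, criterion="distance") - 1
    # relabel in order of first appearance for determinism across permutations
    _, first = np.unique(labels, return_index=True)
    remap = {labels[i]: k for k, i in enumerate(sorted(first))}
    return np.array([remap[l] for l in labels], dtype=int)


def build_sites(locations, labels, season2_of, landscape=None) -> pd.DataFrame:
    """Assemble the per-site table for one animal.

    One row per resting site: centroid (mean of member locations), member
    count per 2-level season (NHS / HS), and landscape covariates evaluated
    at the centroid when a landscape is supplied.
    """
    rows = []
    labels = np.asarray(labels)
    for lab in np.unique(labels):
        members = [loc for loc, l in zip(locations, labels) if l == lab]
        cx = float(np.mean([m.x for m in members]))
        cy = float(np.mean([m.y for m in members]))
        seasons = [season2_of(m.date) for m in members]
        row = dict(site_id=int(lab), animal_id=members[0].animal_id,
                   x=cx, y=cy,
                   n_visits_NHS=sum(s == "NHS" for s in seasons),
                   n_visits_HS=sum(s == "HS" for s in seasons),
                   member_dates=[m.date for m in members])
        if landscape is not None:
            cov = landscape.covariates(cx, cy)
            row.update(veg=int(np.atleast_1d(cov["veg"])[0]),
                       d_village_m=float(np.atleast_1d(cov["d_village_m"])[0]),
                       d_road_m=float(np.atleast_1d(cov["d_road_m"])[0]))
        rows.append(row)
    return pd.DataFrame(rows)


def count_visits(sites: pd.DataFrame) -> dict:
    """Summary: total visits per season, revisit fraction, shared-season sites."""
    n_sites = len(sites)
    n_visits = (sites["n_visits_NHS"] + sites["n_visits_HS"]).to_numpy()
    return {
        "n_sites": int(n_sites),
        "n_visits_total": int(n_visits.sum()),
        "revisited_fraction": float((n_visits > 1).mean()) if n_sites else 0.0,
        "both_season_fraction": float(((sites["n_visits_NHS"] > 0)
                                       & (sites["n_visits_HS"] > 0)).mean())
        if n_sites else 0.0,
    }
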