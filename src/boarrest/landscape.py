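"""Landscape covariates: villages from building footprints, filtered roads,
dense-vegetation classification, signed distances, hunting-season labels.

Villages are derived from building polygons by morphological closing: buffer
each building outward by 50 m, union, then buffer inward by 50 m.  Buildings
whose 50 m buffers touch (i.e. closer than 100 m) merge into one component;
components larger than 1.5 ha are villages.  The road network keeps only the
five high-traffic categories (motorway, trunk, primary, secondary, tertiary).
Distance to village is signed: negative inside a village polygon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as date_t

import numpy as np
import shapely
from shapely.geometry import MultiLineString, MultiPolygon
from shapely.ops import unary_union

log = logging.getLogger("boarrest")

VILLAGE_BUFFER_M = 50.0
VILLAGE_MIN_AREA_M2 = 15_000.0          # 1.5 ha
#: round joins; fixed discretization so the area rule is reproducible
BUFFER_QUAD_SEGS = 16
ROAD_CATEGORIES = {"motorway", "trunk", "primary", "secondary", "tertiary"}

NHS = "NHS"
HS_NONHUNTING = "HS_nonhunting"
HS_HUNTING_DAY = "HS_hunting_day"
SEASON3_LEVELS = (NHS, HS_NONHUNTING, HS_HUNTING_DAY)
#: Wednesday, Saturday, Sunday (datetime.weekday numbering)
DEFAULT_HUNTING_WEEKDAYS = frozenset({2, 5, 6})


def derive_villages(buildings, buffer_m=VILLAGE_BUFFER_M,
                    min_area_m2=VILLAGE_MIN_AREA_M2):
    """Morphological closing of building footprints; keep components > 1.5 ha.

    Returns a list of village polygons.  Idempotent: applying it to its own
    output returns the same polygons (closing is identity on already-closed
    sets and the area rule only removes components).
    """
    if not buildings:
        log.warning("derive_villages: empty building layer")
        return []
    dilated = unary_union([b.buffer(buffer_m, quad_segs=BUFFER_QUAD_SEGS)
                           for b in buildings])
    # components are decided at the dilation stage: buildings whose 50 m
    # buffers overlap (closer than 100 m) form one candidate, which is then
    # shrunk back so its edge matches the peripheral buildings
    comps = (list(dilated.geoms) if dilated.geom_type == "MultiPolygon"
             else [dilated])
    out = []
    for comp in comps:
        eroded = comp.buffer(-buffer_m, quad_segs=BUFFER_QUAD_SEGS)
        if not eroded.is_empty and eroded.area > min_area_m2:
            out.append(eroded)
    return out


def filter_roads(roads, categories=ROAD_CATEGORIES):
    """Keep only the high-traffic road categories.

    ``roads`` is a list of ``(LineString, category)``.  Unknown categories are
    dropped (logged).
    """
    kept, dropped = [], set()
    for line, cat in roads:
        if cat in categories:
            kept.append(line)
        else:
            dropped.add(cat)
    if dropped:
        log.info("filter_roads: dropped categories %s", sorted(dropped))
    if not kept:
        log.warning("filter_roads: no roads left after filtering")
    return kept


@dataclass
class Landscape:
    """Derived landscape layers in a common planar metric CRS."""

    villages: list                # Polygons, each > 1.5 ha
    roads: list                   # LineStrings (filtered)
    vegetation: list              # dense-vegetation Polygons
    extent: tuple = None          # (xmin, ymin, xmax, ymax)
    _vil_union: object = field(default=None, repr=False)
    _road_union: object = field(default=None, repr=False)
    _veg_union: object = field(default=None, repr=False)

    def __post_init__(self):
        self._vil_union = unary_union(self.villages) if self.villages else MultiPolygon()
        self._road_union = unary_union(self.roads) if self.roads else MultiLineString()
        self._veg_union = unary_union(self.vegetation) if self.vegetation else MultiPolygon()

    @classmethod
    def from_raw_layers(cls, raw, extent=None):
        """Build from the raw layers dict of :func:`data_io.load_landscape_layers`."""
        return cls(villages=derive_villages(raw["buildings"]),
                   roads=filter_roads(raw["roads"]),
                   vegetation=list(raw["vegetation"]), extent=extent)

    # -- covariates ---------------------------------------------------------

    def signed_distance_to_village(self, x, y):
        """Distance (m) to the nearest village edge; negative inside a village."""
        if self._vil_union.is_empty:
            raise ValueError("village layer is empty; covariate undefined")
        pts = _as_points(x, y)
        out = shapely.distance(pts, self._vil_union.boundary)
        inside = shapely.covers(self._vil_union, pts)
        out[inside] *= -1.0
        return out if out.size > 1 else float(out[0])

    def distance_to_road(self, x, y):
        """Euclidean distance (m) to the nearest retained road."""
        if self._road_union.is_empty:
            raise ValueError("road layer is empty; covariate undefined")
        out = shapely.distance(_as_points(x, y), self._road_union)
        return out if out.size > 1 else float(out[0])

    def vegetation_class(self, x, y):
        """1 if the point lies within a dense-vegetation patch, else 0."""
        out = shapely.covers(self._veg_union, _as_points(x, y)).astype(int)
        return out if out.size > 1 else int(out[0])

    def covariates(self, x, y):
        """dict of (veg, d_village_m, d_road_m) arrays for point arrays."""
        return {
            "veg": self.vegetation_class(x, y),
            "d_village_m": self.signed_distance_to_village(x, y),
            "d_road_m": self.distance_to_road(x, y),
        }


def _as_points(x, y):
    return shapely.points(np.atleast_1d(np.asarray(x, dtype=float)),
                          np.atleast_1d(np.asarray(y, dtype=float)))


# ---------------------------------------------------------------------------
# Hunting calendar
# ---------------------------------------------------------------------------

@dataclass
class HuntingCalendar:
    """Drive-hunt calendar.

    ``open_periods`` is a list of (open_date, close_date) inclusive intervals
    (the open season runs 15 Aug to end of Feb/Mar, so periods span new year).
    Within the open season, drive hunts are allowed on the configured weekdays
    (default Wed/Sat/Sun) and on bank holidays.
    """

    open_periods: list                       # [(date, date), ...]
    hunting_weekdays: frozenset = DEFAULT_HUNTING_WEEKDAYS
    bank_holidays: frozenset = frozenset()
    coverage: tuple = None                   # (first, last) date covered

    def __post_init__(self):
        for o, c in self.open_periods:
            if not o < c:
                raise ValueError(f"open date {o} not before close date {c}")
        if not self.hunting_weekdays:
            raise ValueError("hunting weekday set is empty")
        if self.coverage is None and self.open_periods:
            first = min(o for o, _ in self.open_periods)
            last = max(c for _, c in self.open_periods)
            self.coverage = (date_t(first.year - 1, 1, 1), date_t(last.year + 1, 12, 31))

    @classmethod
    def default_for_years(cls, years, bank_holidays=(), close_month=2):
        """Seasons opening 15 Aug of each year and closing end Feb (or Mar)
        of the following year."""
        periods = []
        for y in years:
            close_day = 31 if close_month == 3 else (29 if _leap(y + 1) else 28)
            periods.append((date_t(y, 8, 15), date_t(y + 1, close_month, close_day)))
        return cls(periods, bank_holidays=frozenset(bank_holidays))

    def in_open_season(self, d: date_t) -> bool:
        self._check(d)
        return any(o <= d <= c for o, c in self.open_periods)

    def season_label(self, d: date_t) -> str:
        """3-level label: NHS / HS_nonhunting / HS_hunting_day."""
        if not self.in_open_season(d):
            return NHS
        if d.weekday() in self.hunting_weekdays or d in self.bank_holidays:
            return HS_HUNTING_DAY
        return HS_NONHUNTING

    def season2(self, d: date_t) -> str:
        """2-level label collapsing hunting/non-hunting days: NHS / HS."""
        return "HS" if self.in_open_season(d) else NHS

    def _check(self, d):
        if self.coverage and not (self.coverage[0] <= d <= self.coverage[1]):
            raise ValueError(f"date {d} outside calendar coverage {self.coverage}")


def _leap(y):
    return y % 4 == 0 and (y % 100 != 0 or y % 400 == 0)
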