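"""Readers/writers for collar sensor tables and vector landscape layers.

Sensor input is delimited text: an activity table (``animal_id, timestamp,
act``) sampled every 5 min and a GPS table (``animal_id, timestamp, lon, lat``
or ``x, y``) sampled every 30 min.  All geometry downstream is planar and
metric, so geographic coordinates are projected with a Lambert conformal conic
projection (defaults reproduce the Lambert-93 grid used for metropolitan
France, on the GRS80 ellipsoid).

Timestamps are stored timezone-naive in UTC; local civil time enters only for
sunrise/sunset anchoring (see :mod:`boarrest.segmentation`).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon, mapping, shape
from shapely.validation import make_valid

log = logging.getLogger("boarrest")

ACT_CADENCE = timedelta(minutes=5)
GPS_CADENCE = timedelta(minutes=30)
#: sensor gaps up to this many nominal intervals are tolerated silently
GAP_TOLERANCE_INTERVALS = 3
DEFAULT_EXCLUSION_DAYS = 3


class SchemaError(ValueError):
    """A required column is missing from an input table."""


# ---------------------------------------------------------------------------
# Planar projection
# ---------------------------------------------------------------------------

class LambertConformalConic:
    """Ellipsoidal Lambert conformal conic projection (2SP form).

    Default parameters are those of the French Lambert-93 grid (RGF93):
    standard parallels 44° and 49° N, origin 46.5° N / 3° E, false easting
    700 000 m, false northing 6 600 000 m, GRS80 ellipsoid.  Suitable for any
    mid-latitude study area after changing the parallels and origin.
    """

    def __init__(self, lat_1=44.0, lat_2=49.0, lat_0=46.5, lon_0=3.0,
                 x_0=700_000.0, y_0=6_600_000.0,
                 a=6_378_137.0, f=1 / 298.257222101):
        self.params = dict(lat_1=lat_1, lat_2=lat_2, lat_0=lat_0, lon_0=lon_0,
                           x_0=x_0, y_0=y_0, a=a, f=f)
        e2 = f * (2 - f)
        self._e = math.sqrt(e2)
        self._a, self._x0, self._y0 = a, x_0, y_0
        self._lon0 = math.radians(lon_0)
        p1, p2, p0 = (math.radians(v) for v in (lat_1, lat_2, lat_0))
        m1, m2 = self._m(p1), self._m(p2)
        t0, t1, t2 = self._t(p0), self._t(p1), self._t(p2)
        if abs(lat_1 - lat_2) < 1e-12:
            self._n = math.sin(p1)
        else:
            self._n = (math.log(m1) - math.log(m2)) / (math.log(t1) - math.log(t2))
        self._F = m1 / (self._n * t1 ** self._n)
        self._rho0 = a * self._F * t0 ** self._n

    def _m(self, phi):
        s = math.sin(phi)
        return math.cos(phi) / math.sqrt(1 - self._e ** 2 * s * s)

    def _t(self, phi):
        e, s = self._e, math.sin(phi)
        return math.tan(math.pi / 4 - phi / 2) / ((1 - e * s) / (1 + e * s)) ** (e / 2)

    def forward(self, lon, lat):
        """Geographic degrees -> planar meters (x, y)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        phi = np.radians(lat)
        e, n = self._e, self._n
        s = np.sin(phi)
        t = np.tan(np.pi / 4 - phi / 2) / ((1 - e * s) / (1 + e * s)) ** (e / 2)
        rho = self._a * self._F * t ** n
        theta = n * (np.radians(lon) - self._lon0)
        x = self._x0 + rho * np.sin(theta)
        y = self._y0 + self._rho0 - rho * np.cos(theta)
        return x, y

    def inverse(self, x, y):
        """Planar meters -> geographic degrees (lon, lat)."""
        x = np.asarray(x, dtype=float) - self._x0
        yp = self._rho0 - (np.asarray(y, dtype=float) - self._y0)
        e, n = self._e, self._n
        rho = np.sign(n) * np.hypot(x, yp)
        t = (rho / (self._a * self._F)) ** (1 / n)
        theta = np.arctan2(np.sign(n) * x, np.sign(n) * yp)
        lon = np.degrees(theta / n + self._lon0)
        phi = np.pi / 2 - 2 * np.arctan(t)
        for _ in range(8):
            s = np.sin(phi)
            phi = np.pi / 2 - 2 * np.arctan(t * ((1 - e * s) / (1 + e * s)) ** (e / 2))
        return lon, np.degrees(phi)


#: sentinel projection meaning "input coordinates are already planar meters"
IDENTITY_PROJECTION = None


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

def _gap_intervals(times: np.ndarray, cadence: timedelta) -> list[tuple]:
    """Intervals between consecutive samples exceeding the tolerated gap."""
    if len(times) < 2:
        return []
    dt = np.diff(times)
    limit = np.timedelta64(int(cadence.total_seconds() * GAP_TOLERANCE_INTERVALS), "s")
    idx = np.nonzero(dt > limit)[0]
    return [(times[i], times[i + 1]) for i in idx]


@dataclass
class ActSeries:
    """Activity series at nominal 5-min cadence, one animal.

    ``act`` is the dimensionless 0-255 collar activity summary (anteroposterior
    axis).  Timestamps are UTC (naive), strictly increasing.
    """

    animal_id: str
    times: np.ndarray            # datetime64[s]
    act: np.ndarray              # int, 0..255
    gaps: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.act = np.asarray(self.act)
        if len(self.times) != len(self.act):
            raise ValueError("times and act length mismatch")
        if len(self.times) > 1 and not (np.diff(self.times) > np.timedelta64(0, "s")).all():
            raise ValueError("timestamps must be strictly increasing")
        if len(self.act) and ((self.act < 0) | (self.act > 255)).any():
            raise ValueError("act values outside [0, 255]")
        if not self.gaps:
            self.gaps = _gap_intervals(self.times, ACT_CADENCE)


@dataclass
class GpsTrack:
    """GPS fixes in a planar metric CRS, nominal 30-min cadence, one animal."""

    animal_id: str
    times: np.ndarray            # datetime64[s]
    x: np.ndarray                # meters
    y: np.ndarray
    crs: str = "local-metric"
    gaps: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times/x/y length mismatch")
        if len(self.times) > 1 and not (np.diff(self.times) > np.timedelta64(0, "s")).all():
            raise ValueError("timestamps must be strictly increasing")
        if len(self.x) and not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")
        if not self.gaps:
            self.gaps = _gap_intervals(self.times, GPS_CADENCE)


@dataclass
class AnimalRecord:
    """Per-animal survey bookkeeping.

    The survey starts ``exclusion_days`` after capture (post-capture behaviour
    is atypical and excluded) and ``survey_length_days`` measures the usable
    monitoring window.
    """

    animal_id: str
    site_id: str
    sex: str
    capture_time: datetime
    survey_start: datetime
    survey_end: datetime

    @property
    def survey_length_days(self) -> float:
        return (self.survey_end - self.survey_start).total_seconds() / 86400.0

    def __post_init__(self):
        if self.survey_length_days <= 0:
            raise ValueError("survey_length_days must be > 0")


# ---------------------------------------------------------------------------
# Sensor tables
# ---------------------------------------------------------------------------

def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _parse_times(df: pd.DataFrame, path) -> pd.DataFrame:
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    bad = ts.isna()
    if bad.any():
        log.warning("%s: dropped %d rows with unparseable timestamps", path, int(bad.sum()))
    df = df.loc[~bad].copy()
    df["timestamp"] = ts[~bad].dt.tz_localize(None)
    return df


def load_sensor_tables(act_path, gps_path, animals_path=None,
                       projection=IDENTITY_PROJECTION,
                       exclusion_days: int = DEFAULT_EXCLUSION_DAYS):
    """Load ACT + GPS tables, assemble per-animal records, apply the
    post-capture exclusion window.

    Returns a dict ``animal_id -> (ActSeries, GpsTrack, AnimalRecord)``.
    ``animals_path`` is an optional CSV (animal_id, site_id, sex,
    capture_time); absent, capture is taken as the first sensor timestamp and
    site/sex are unknown.  Rows before ``capture + exclusion_days`` are
    dropped (counts logged).
    """
    act_df = _parse_times(pd.read_csv(act_path), act_path)
    _require(act_df, ["animal_id", "timestamp", "act"], act_path)
    if ((act_df["act"] < 0) | (act_df["act"] > 255)).any():
        raise ValueError(f"{act_path}: act values outside [0, 255]")
    gps_df = _parse_times(pd.read_csv(gps_path), gps_path)
    _require(gps_df, ["animal_id", "timestamp"], gps_path)
    if {"lon", "lat"}.issubset(gps_df.columns):
        if projection is not IDENTITY_PROJECTION:
            gps_df["x"], gps_df["y"] = projection.forward(
                gps_df["lon"].to_numpy(), gps_df["lat"].to_numpy())
        else:
            gps_df["x"], gps_df["y"] = gps_df["lon"], gps_df["lat"]
    _require(gps_df, ["x", "y"], gps_path)

    meta = {}
    if animals_path is not None:
        adf = pd.read_csv(animals_path)
        _require(adf, ["animal_id", "capture_time"], animals_path)
        for _, r in adf.iterrows():
            meta[str(r["animal_id"])] = dict(
                site_id=str(r.get("site_id", "site0")),
                sex=str(r.get("sex", "unknown")),
                capture_time=pd.Timestamp(r["capture_time"]).to_pydatetime(),
            )

    out = {}
    for aid in sorted(set(act_df["animal_id"].astype(str)) | set(gps_df["animal_id"].astype(str))):
        a = act_df[act_df["animal_id"].astype(str) == aid].sort_values("timestamp")
        g = gps_df[gps_df["animal_id"].astype(str) == aid].sort_values("timestamp")
        m = meta.get(aid)
        if m is None:
            # capture time unknown: no exclusion window can be applied
            first = min([t for t in (a["timestamp"].min(), g["timestamp"].min())
                         if pd.notna(t)])
            m = dict(site_id="site0", sex="unknown",
                     capture_time=first.to_pydatetime() - timedelta(days=exclusion_days))
        start = m["capture_time"] + timedelta(days=exclusion_days)
        end_candidates = [t for t in (a["timestamp"].max(), g["timestamp"].max()) if pd.notna(t)]
        end = max(end_candidates).to_pydatetime() + timedelta(minutes=5)
        n_drop = int((a["timestamp"] < start).sum() + (g["timestamp"] < start).sum())
        if n_drop:
            log.info("animal %s: dropped %d rows before survey start %s", aid, n_drop, start)
        a = a[a["timestamp"] >= start]
        g = g[g["timestamp"] >= start]
        rec = AnimalRecord(aid, m["site_id"], m["sex"], m["capture_time"], start, end)
        out[aid] = (
            ActSeries(aid, a["timestamp"].to_numpy(), a["act"].to_numpy()),
            GpsTrack(aid, g["timestamp"].to_numpy(), g["x"].to_numpy(dtype=float),
                     g["y"].to_numpy(dtype=float)),
            rec,
        )
    return out


def write_act_csv(series: ActSeries, path) -> None:
    pd.DataFrame({"animal_id": series.animal_id,
                  "timestamp": series.times.astype("datetime64[s]").astype(str),
                  "act": series.act}).to_csv(path, index=False)


def write_gps_csv(track: GpsTrack, path) -> None:
    pd.DataFrame({"animal_id": track.animal_id,
                  "timestamp": track.times.astype("datetime64[s]").astype(str),
                  "x": track.x, "y": track.y}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Vector layers (GeoJSON)
# ---------------------------------------------------------------------------

def _repair(geom):
    if geom.is_valid:
        return geom
    fixed = make_valid(geom)
    if fixed.geom_type == "GeometryCollection":
        polys = [g for g in fixed.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        if polys:
            from shapely.ops import unary_union
            fixed = unary_union(polys)
    log.warning("repaired invalid geometry (%s)", geom.geom_type)
    return fixed


def load_landscape_layers(buildings_path=None, roads_path=None, vegetation_path=None,
                          projection=IDENTITY_PROJECTION):
    """Load raw vector layers from GeoJSON files.

    Returns a dict with keys ``buildings`` (list of Polygon), ``roads``
    (list of (LineString, category)), ``vegetation`` (list of Polygon), all in
    the common planar CRS.  Invalid polygons are repaired (logged); mixed
    geometry types within a layer raise.
    """
    def read(path, expect):
        if path is None:
            return []
        with open(path) as fh:
            gj = json.load(fh)
        feats = gj.get("features", [])
        out = []
        for f in feats:
            geom = shape(f["geometry"])
            if geom.geom_type == "Multi" + expect:
                geoms = list(geom.geoms)
            elif geom.geom_type == expect:
                geoms = [geom]
            else:
                raise ValueError(f"{path}: mixed geometry type {geom.geom_type}, expected {expect}")
            for g in geoms:
                if expect == "Polygon":
                    g = _repair(g)
                if projection is not IDENTITY_PROJECTION:
                    g = _project_geom(g, projection)
                out.append((g, f.get("properties", {})))
        if not feats:
            log.warning("%s: empty layer", path)
        return out

    buildings = [g for g, _ in read(buildings_path, "Polygon")]
    roads = [(g, p.get("category", "")) for g, p in read(roads_path, "LineString")]
    vegetation = [g for g, _ in read(vegetation_path, "Polygon")]
    return {"buildings": buildings, "roads": roads, "vegetation": vegetation}


def _project_geom(geom, projection):
    from shapely.ops import transform
    return transform(lambda x, y: projection.forward(x, y), geom)


def write_geojson(path, geoms, properties=None) -> None:
    """Write geometries (+parallel property dicts) as a GeoJSON FeatureCollection."""
    properties = properties or [{} for _ in geoms]
    feats = [{"type": "Feature", "geometry": mapping(g), "properties": p}
             for g, p in zip(geoms, properties)]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
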