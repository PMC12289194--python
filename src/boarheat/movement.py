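"""GPS fix filtering and daily movement metrics.

Fix quality is screened by dilution of precision: fixes are retained when
1 <= DOP <= 7 (inclusive on both ends).  Three metrics summarise each
animal's biological day:

* daily distance travelled — sum of great-circle step lengths;
* maximum daily net squared displacement (NSD) — the largest squared
  great-circle distance from the day's first fix;
* daily mean speed — mean of step length / step duration.

Distances use the haversine formula on a sphere of radius 6371.0 km; over
a study area of a few kilometres the spherical-vs-ellipsoidal difference
is far below GPS error.  Steps whose duration exceeds a gap cap (default
4x the nominal fix interval) are excluded from distance and speed — a long
silent interval says nothing about the path — but not from NSD, which only
needs the fix positions themselves.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import solartime

__all__ = ["EARTH_RADIUS_M", "haversine_m", "read_gps_csv", "filter_dop", "daily_metrics"]

log = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0
DOP_MIN, DOP_MAX = 1.0, 7.0


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres between coordinate pairs (degrees)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def read_gps_csv(path) -> pd.DataFrame:
    """Read a GPS CSV with columns animal_id?, timestamp/t, lat, lon, dop."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    tcol = cols.get("t") or cols.get("timestamp")
    if tcol is None or not {"lat", "lon", "dop"} <= set(cols):
        raise ValueError("GPS CSV needs columns: timestamp/t, lat, lon, dop")
    out = pd.DataFrame(
        {
            "t": pd.to_datetime(df[tcol]),
            "lat": df[cols["lat"]].astype(float),
            "lon": df[cols["lon"]].astype(float),
            "dop": df[cols["dop"]].astype(float),
        }
    )
    if "animal_id" in cols:
        out.insert(0, "animal_id", df[cols["animal_id"]])
    return out


def filter_dop(fixes: pd.DataFrame) -> pd.DataFrame:
    """Retain fixes with 1 <= DOP <= 7 (inclusive); log the removal count."""
    if "dop" not in fixes.columns or fixes["dop"].isna().any():
        raise ValueError("every fix needs a DOP value")
    keep = (fixes["dop"] >= DOP_MIN) & (fixes["dop"] <= DOP_MAX)
    removed = int((~keep).sum())
    if removed:
        log.info("filter_dop: removed %d of %d fixes outside [1, 7]", removed, len(fixes))
    return fixes[keep].reset_index(drop=True)


def daily_metrics(
    fixes: pd.DataFrame,
    solar: pd.DataFrame,
    gap_cap_min: float | None = None,
    nominal_interval_min: float = 30.0,
) -> pd.DataFrame:
    """Per-animal, per-biological-day movement metrics from filtered fixes.

    Returns columns: ``animal_id, bio_day, distance_m, max_nsd_m2,
    mean_speed_ms, n_fixes``.  Days with a single fix report zero distance
    and NSD and NaN-free zero speed.
    """
    if gap_cap_min is None:
        gap_cap_min = 4.0 * nominal_interval_min
    df = fixes.copy()
    if "animal_id" not in df.columns:
        df["animal_id"] = "A01"
    rows = []
    for aid, grp in df.groupby("animal_id", sort=True):
        t = grp["t"].to_numpy(dtype="datetime64[ns]")
        if len(t) > 1 and not (np.diff(t) > np.timedelta64(0, "ns")).all():
            raise ValueError(f"fixes for {aid} not strictly increasing in time")
        bio = solartime.assign_bio_day(grp["t"], solar)
        grp = grp.assign(bio_day=bio)
        for day, sub in grp.groupby("bio_day", sort=True):
            lat = sub["lat"].to_numpy(dtype=float)
            lon = sub["lon"].to_numpy(dtype=float)
            ts = sub["t"].to_numpy(dtype="datetime64[ns]")
            n = len(sub)
            if n <= 1:
                rows.append((aid, day, 0.0, 0.0, 0.0, n))
                continue
            step = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
            dt_s = np.diff(ts).astype("timedelta64[s]").astype(float)
            ok = dt_s <= gap_cap_min * 60.0
            nsd = haversine_m(lat[0], lon[0], lat, lon) ** 2
            dist = float(step[ok].sum())
            speed = float((step[ok] / dt_s[ok]).mean()) if ok.any() else 0.0
            rows.append((aid, day, dist, float(nsd.max()), speed, n))
    return pd.DataFrame(
        rows,
        columns=["animal_id", "bio_day", "distance_m", "max_nsd_m2", "mean_speed_ms", "n_fixes"],
    )
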