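"""Hourly weather ingest, binary precipitation coding and daily aggregation.

Because a large share of summer days carry no rain at all (about 42% in the
conditions this package targets), precipitation enters the models as a
binary presence/absence factor at each temporal scale: an hour (or day, or
heatwave period) is "presence" iff its total precipitation is strictly
greater than 0 mm.  No trace threshold is applied.

Daily aggregation uses the same sunrise-anchored biological days as the
activity data, keeping response and covariates on one clock; a
calendar-day mode is available for comparison with providers that report
midnight-to-midnight days.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import solartime

__all__ = ["read_weather_csv", "precip_binary", "daily_weather", "join_weather"]

log = logging.getLogger(__name__)

TEMP_SANITY = (-40.0, 50.0)


def read_weather_csv(path) -> pd.DataFrame:
    """Read an hourly weather CSV, tolerant of provider-style headers.

    Accepts ``t``/``datetime``/``timestamp`` for time, ``temp``/
    ``temperature`` (degrees C) and ``precip``/``precipitation`` (mm).
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    tcol = cols.get("t") or cols.get("datetime") or cols.get("timestamp")
    tempcol = cols.get("temp") or cols.get("temperature")
    pcol = cols.get("precip") or cols.get("precipitation")
    if tcol is None or tempcol is None or pcol is None:
        raise ValueError("weather CSV needs time, temperature and precipitation columns")
    out = pd.DataFrame(
        {
            "t": pd.to_datetime(df[tcol]),
            "temp": df[tempcol].astype(float),
            "precip": df[pcol].astype(float),
        }
    )
    if (out["precip"] < 0).any():
        raise ValueError("negative precipitation")
    lo, hi = TEMP_SANITY
    if ((out["temp"] < lo) | (out["temp"] > hi)).any():
        raise ValueError(f"temperature outside sanity bounds {TEMP_SANITY}")
    return out


def precip_binary(total) -> np.ndarray | int:
    """Binary precipitation coding: 1 ("presence") iff total > 0 mm, strictly.

    Accepts a scalar or array of non-negative totals in mm.
    """
    arr = np.asarray(total, dtype=float)
    if (arr < 0).any():
        raise ValueError("precipitation total must be >= 0")
    out = (arr > 0.0).astype(int)
    return int(out) if np.isscalar(total) or arr.ndim == 0 else out


def daily_weather(
    hours: pd.DataFrame, solar: pd.DataFrame | None = None, calendar_days: bool = False
) -> pd.DataFrame:
    """Aggregate hourly weather to days.

    By default hours are grouped into sunrise-anchored biological days
    (requires a solar table); with ``calendar_days=True`` plain dates are
    used instead.  Hour midpoints decide day membership so an hour is never
    split.

    Returns columns: ``bio_day, temp_mean, temp_max, precip_total,
    precip_presence, hours_covered``.
    """
    t = pd.DatetimeIndex(hours["t"])
    if calendar_days:
        day = t.date
    else:
        if solar is None:
            raise ValueError("solar table required unless calendar_days=True")
        day = solartime.assign_bio_day(t + pd.Timedelta(minutes=30), solar)
    df = pd.DataFrame(
        {
            "bio_day": day,
            "temp": hours["temp"].to_numpy(dtype=float),
            "precip": hours["precip"].to_numpy(dtype=float),
        }
    )
    agg = (
        df.groupby("bio_day", sort=True)
        .agg(
            temp_mean=("temp", "mean"),
            temp_max=("temp", "max"),
            precip_total=("precip", "sum"),
            hours_covered=("temp", "size"),
        )
        .reset_index()
    )
    agg["precip_presence"] = precip_binary(agg["precip_total"].to_numpy())
    return agg[
        ["bio_day", "temp_mean", "temp_max", "precip_total", "precip_presence", "hours_covered"]
    ]


def join_weather(activity: pd.DataFrame, weather: pd.DataFrame, on: list[str] | None = None) -> pd.DataFrame:
    """Inner-join an activity table with weather on shared keys.

    For hourly activity join on ``t_hour`` vs the weather hour ``t``; for
    daily activity join on ``bio_day``.  Unmatched activity rows are
    dropped and counted; an empty intersection is an error.
    """
    if on is None:
        on = ["t_hour"] if "t_hour" in activity.columns else ["bio_day"]
    w = weather.copy()
    if on == ["t_hour"] and "t" in w.columns and "t_hour" not in w.columns:
        w = w.rename(columns={"t": "t_hour"})
    merged = activity.merge(w, on=on, how="inner")
    dropped = len(activity) - len(merged)
    if len(merged) == 0:
        raise ValueError(f"no overlap between activity and weather on {on}")
    if dropped:
        log.info("join_weather: dropped %d activity row(s) without weather", dropped)
    return merged
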