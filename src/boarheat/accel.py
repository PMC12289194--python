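"""VeDBA from raw triaxial acceleration, and hourly/daily activity summaries.

The vectorial sum of dynamic body acceleration (VeDBA) is the Euclidean
norm of the three gravity-removed acceleration components and serves as a
proxy for movement-based energy expenditure.  Processing follows the
standard tag-software convention:

1. the static (gravitational) component per axis is a centred rolling mean
   over a 2 s window (21 samples at 10 Hz);
2. per-sample VeDBA = sqrt(sum over axes of (raw - static)^2);
3. the smoothed VeDBA is a second centred 2 s rolling mean of that norm.

Edges use shrinking windows (no samples dropped at stream or hour
boundaries) and rolling windows never bridge recording gaps longer than
1 s.  Units are g throughout.

Summaries are anchored on sunrise-to-sunrise biological days: the smoothed
VeDBA is summed per calendar hour, each hour labelled with the biological
day its samples fall in, then averaged per day.  Hours with poor sample
coverage and days with too few complete hours are flagged and excluded
from the daily means (thresholds configurable; the defaults of 0.8 hour
coverage and 20 h/day are this package's own missing-data policy).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import solartime

__all__ = [
    "read_accel_csv",
    "static_component",
    "vedba",
    "hourly_summary",
    "daily_summary",
    "hourly_from_simulated",
]

log = logging.getLogger(__name__)

GAP_BREAK_S = 1.0  # rolling windows never span gaps longer than this


def read_accel_csv(path) -> pd.DataFrame:
    """Read a raw accelerometer CSV with columns timestamp, ax, ay, az (g)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    tcol = cols.get("t") or cols.get("timestamp")
    if tcol is None or not {"ax", "ay", "az"} <= set(cols):
        raise ValueError("accelerometer CSV needs columns: timestamp/t, ax, ay, az")
    out = pd.DataFrame(
        {
            "t": pd.to_datetime(df[tcol]),
            "ax": df[cols["ax"]].astype(float),
            "ay": df[cols["ay"]].astype(float),
            "az": df[cols["az"]].astype(float),
        }
    )
    return out


def _window_samples(window_s: float, hz: float) -> int:
    n = int(round(window_s * hz))
    return max(n + 1 if n % 2 == 0 else n, 1)  # nearest odd, >= 1


def _check_stream(stream: pd.DataFrame) -> None:
    t = stream["t"].to_numpy(dtype="datetime64[ns]")
    if len(t) > 1 and not (np.diff(t) > np.timedelta64(0, "ns")).all():
        raise ValueError("timestamps must be strictly increasing")


def _segments(t: np.ndarray) -> np.ndarray:
    """Segment ids; a new segment starts after any inter-sample gap > 1 s."""
    if len(t) == 0:
        return np.array([], dtype=int)
    dt = np.diff(t).astype("timedelta64[ns]").astype(np.int64) / 1e9
    return np.concatenate([[0], np.cumsum(dt > GAP_BREAK_S)])


def _rolling_centred(x: pd.Series, n: int) -> pd.Series:
    return x.rolling(n, center=True, min_periods=1).mean()


def static_component(stream: pd.DataFrame, window_s: float = 2.0, hz: float = 10.0) -> pd.DataFrame:
    """Per-axis static (gravitational) acceleration by centred rolling mean.

    Edges of each contiguous segment use shrinking windows; gaps > 1 s
    break the window so smoothing never crosses a recording dropout.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if stream.empty:
        return stream.loc[:, ["t", "ax", "ay", "az"]].copy()
    _check_stream(stream)
    n = _window_samples(window_s, hz)
    seg = _segments(stream["t"].to_numpy(dtype="datetime64[ns]"))
    out = {"t": stream["t"].to_numpy()}
    g = pd.Series(seg, index=stream.index)
    for axis in ("ax", "ay", "az"):
        out[axis] = (
            stream[axis].groupby(g, sort=False).transform(lambda s: _rolling_centred(s, n)).to_numpy()
        )
    return pd.DataFrame(out)


def vedba(stream: pd.DataFrame, window_s: float = 2.0, hz: float = 10.0) -> pd.DataFrame:
    """Per-sample VeDBA and its 2 s centred smoothing.

    Returns columns ``t``, ``vedba`` and ``vedba_smoothed``; both series are
    non-negative and exactly zero for any constant input stream.
    """
    if stream.empty:
        return pd.DataFrame(columns=["t", "vedba", "vedba_smoothed"])
    static = static_component(stream, window_s=window_s, hz=hz)
    dyn = stream[["ax", "ay", "az"]].to_numpy(dtype=float) - static[["ax", "ay", "az"]].to_numpy()
    v = np.sqrt((dyn**2).sum(axis=1))
    seg = _segments(stream["t"].to_numpy(dtype="datetime64[ns]"))
    n = _window_samples(window_s, hz)
    sm = (
        pd.Series(v)
        .groupby(pd.Series(seg), sort=False)
        .transform(lambda s: _rolling_centred(s, n))
        .to_numpy()
    )
    return pd.DataFrame({"t": stream["t"].to_numpy(), "vedba": v, "vedba_smoothed": sm})


def hourly_summary(
    series: pd.DataFrame,
    solar: pd.DataFrame,
    hz: float = 10.0,
    coverage_threshold: float = 0.8,
    animal_id: str | None = None,
) -> pd.DataFrame:
    """Hourly sums of smoothed VeDBA on biological days.

    Samples are grouped by calendar hour; each group is labelled with the
    biological day its samples belong to (so the hour containing sunrise
    yields two partial rows, one per adjacent biological day — these fall
    below the coverage threshold and are excluded from daily means).

    Returns columns: ``animal_id`` (if given), ``bio_day``, ``t_hour``
    (hour start, local), ``clock_hour``, ``vedba_sum``, ``coverage``,
    ``complete``.
    """
    if series.empty:
        raise ValueError("empty VeDBA series")
    t = pd.DatetimeIndex(series["t"])
    bio = solartime.assign_bio_day(series["t"], solar)
    df = pd.DataFrame(
        {
            "bio_day": bio,
            "t_hour": t.floor("h"),
            "vedba_smoothed": series["vedba_smoothed"].to_numpy(dtype=float),
        }
    )
    grouped = df.groupby(["bio_day", "t_hour"], sort=True, observed=True)["vedba_smoothed"].agg(
        ["sum", "count"]
    )
    out = grouped.reset_index().rename(columns={"sum": "vedba_sum"})
    out["clock_hour"] = pd.DatetimeIndex(out["t_hour"]).hour
    out["coverage"] = out["count"] / (3600.0 * hz)
    out["complete"] = out["coverage"] >= coverage_threshold
    n_flag = int((~out["complete"]).sum())
    if n_flag:
        log.info("hourly_summary: %d hour(s) below coverage %.2f flagged", n_flag, coverage_threshold)
    out = out.drop(columns="count")
    if animal_id is not None:
        out.insert(0, "animal_id", animal_id)
    cols = (["animal_id"] if animal_id is not None else []) + [
        "bio_day",
        "t_hour",
        "clock_hour",
        "vedba_sum",
        "coverage",
        "complete",
    ]
    return out[cols]


def daily_summary(hourly: pd.DataFrame, min_hours: int = 20) -> pd.DataFrame:
    """Daily mean of the complete hourly sums, per animal and biological day.

    Days with fewer than ``min_hours`` complete hours are flagged
    ``included=False`` (and should be excluded from modelling).
    """
    if "bio_day" not in hourly.columns:
        raise ValueError("hourly table must carry bio_day labels")
    df = hourly[hourly["complete"]] if "complete" in hourly.columns else hourly
    keys = (["animal_id"] if "animal_id" in df.columns else []) + ["bio_day"]
    agg = df.groupby(keys, sort=True, observed=True)["vedba_sum"].agg(["mean", "count"]).reset_index()
    agg = agg.rename(columns={"mean": "vedba_daily_mean", "count": "hours_present"})
    agg["doy"] = pd.to_datetime(agg["bio_day"]).dt.dayofyear
    agg["included"] = agg["hours_present"] >= min_hours
    n_excl = int((~agg["included"]).sum())
    if n_excl:
        log.info("daily_summary: %d day(s) with < %d h excluded", n_excl, min_hours)
    return agg


def hourly_from_simulated(sim_hourly: pd.DataFrame, solar: pd.DataFrame) -> pd.DataFrame:
    """Adapt the simulator's hourly-fidelity output to the HourlyActivity schema.

    Each hour is assigned to the biological day containing its midpoint and
    marked complete with coverage 1 (the simulator emits whole hours).
    """
    t = pd.DatetimeIndex(sim_hourly["t"])
    out = pd.DataFrame(
        {
            "animal_id": sim_hourly["animal_id"].to_numpy(),
            "bio_day": solartime.assign_bio_day(t + pd.Timedelta(minutes=30), solar),
            "t_hour": t,
            "clock_hour": t.hour,
            "vedba_sum": sim_hourly["vedba_sum"].to_numpy(dtype=float),
            "coverage": 1.0,
            "complete": True,
        }
    )
    return out
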