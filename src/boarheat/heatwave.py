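"""Heatwave detection from daily temperature, and the heatwave model table.

A heatwave here is tied to the upper end of the species' summer
thermoneutral zone (about 24 degrees C for wild boar): a day *qualifies*
when its mean temperature over the biological day strictly exceeds the
threshold and at least 23 of its hours carry data (so a near-complete day
of evidence backs the mean).  A heatwave is a maximal run of one or more
consecutive qualifying days; single-day events count, and lengths are
reported in whole days.

The "23+ h" requirement is read as per-day data coverage, not a rolling
23-hour temperature window — heatwave durations are integer day counts,
which only a day-level definition produces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Heatwave", "detect_heatwaves", "heatwave_table"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Heatwave:
    """A maximal run of consecutive qualifying hot days."""

    start_day: object  # date
    end_day: object  # date, inclusive
    length_days: int


def detect_heatwaves(
    daily: pd.DataFrame, threshold_c: float = 24.0, min_hours: int = 23
) -> list[Heatwave]:
    """Find maximal runs of qualifying days in a daily weather table.

    A day qualifies iff ``hours_covered >= min_hours`` and
    ``temp_mean > threshold_c`` (strict).  Runs are broken by calendar
    gaps in ``bio_day`` as well as by non-qualifying days; gaps are logged.
    """
    if daily.empty:
        return []
    df = daily.sort_values("bio_day").reset_index(drop=True)
    days = pd.to_datetime(df["bio_day"])
    qual = (df["hours_covered"].to_numpy() >= min_hours) & (
        df["temp_mean"].to_numpy(dtype=float) > threshold_c
    )
    gap_after = np.concatenate([np.diff(days.to_numpy()) > np.timedelta64(1, "D"), [True]])
    n_gaps = int(gap_after[:-1].sum())
    if n_gaps:
        log.info("detect_heatwaves: %d gap(s) in day sequence split runs", n_gaps)

    waves: list[Heatwave] = []
    run_start: int | None = None

    def close(end_i: int) -> None:
        nonlocal run_start
        waves.append(
            Heatwave(
                start_day=df["bio_day"].iloc[run_start],
                end_day=df["bio_day"].iloc[end_i],
                length_days=end_i - run_start + 1,
            )
        )
        run_start = None

    for i in range(len(df)):
        if qual[i]:
            if run_start is None:
                run_start = i
            if gap_after[i]:  # sequence gap (or table end) terminates the run
                close(i)
        elif run_start is not None:
            close(i - 1)
    return waves


def heatwave_table(
    heatwaves: list[Heatwave], daily_weather: pd.DataFrame, daily_activity: pd.DataFrame
) -> pd.DataFrame:
    """One row per animal x heatwave: the mixed-model input table.

    Columns: ``heatwave_id, start_day, end_day, length_days, tmax_mean``
    (mean of the period's daily maxima), ``precip_presence`` (1 iff any
    precipitation fell during the period) and ``vedba_mean`` (the animal's
    mean of daily mean VeDBA over the period).  Animals without activity
    inside a period are omitted.
    """
    dw = daily_weather.set_index(pd.to_datetime(daily_weather["bio_day"]))
    act = daily_activity.copy()
    if "included" in act.columns:
        act = act[act["included"]]
    act["_day"] = pd.to_datetime(act["bio_day"])
    rows = []
    for k, hw in enumerate(heatwaves):
        span = pd.date_range(pd.Timestamp(hw.start_day), pd.Timestamp(hw.end_day), freq="D")
        wsub = dw.loc[dw.index.isin(span)]
        tmax_mean = float(wsub["temp_max"].mean())
        precip = int(wsub["precip_total"].sum() > 0)
        asub = act[act["_day"].isin(span)]
        for aid, grp in asub.groupby("animal_id"):
            rows.append(
                {
                    "heatwave_id": k,
                    "animal_id": aid,
                    "start_day": hw.start_day,
                    "end_day": hw.end_day,
                    "length_days": hw.length_days,
                    "tmax_mean": tmax_mean,
                    "precip_presence": precip,
                    "vedba_mean": float(grp["vedba_daily_mean"].mean()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "heatwave_id",
            "animal_id",
            "start_day",
            "end_day",
            "length_days",
            "tmax_mean",
            "precip_presence",
            "vedba_mean",
        ],
    )
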