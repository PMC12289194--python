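"""Sunrise/sunset computation and sunrise-anchored biological days.

Nocturnal species are awkward to analyse on midnight-to-midnight calendar
days: a single active (night) phase is split across two dates.  This module
defines a *biological day* running from sunrise on day ``d`` to the next
sunrise on day ``d + 1``, so that each day holds one complete daylight
resting phase followed by one complete night active phase.

Sun positions come from the NOAA solar-position equations (Meeus-derived
low-accuracy ephemeris, good to well under a minute for sunrise/sunset at
temperate latitudes).  Events use the conventional solar elevation of
-0.833 degrees (atmospheric refraction plus the solar half-disc).

All timestamps are naive local clock times under a fixed UTC offset; the
summer study windows this package targets contain no DST transitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "NoSunEventError",
    "SolarDay",
    "solar_elevation",
    "solar_events",
    "solar_table",
    "assign_bio_day",
    "day_night",
]

#: solar elevation (degrees) defining sunrise/sunset: refraction + half disc
RISE_SET_ELEVATION = -0.833


class NoSunEventError(ValueError):
    """Raised when the sun does not cross the horizon on a date (polar day/night)."""


@dataclass(frozen=True)
class SolarDay:
    """Sunrise and sunset (local clock time) for one calendar date."""

    date: _date
    sunrise: pd.Timestamp
    sunset: pd.Timestamp


def _julian_day(dt_utc: datetime) -> float:
    y, m = dt_utc.year, dt_utc.month
    d = (
        dt_utc.day
        + dt_utc.hour / 24.0
        + dt_utc.minute / 1440.0
        + (dt_utc.second + dt_utc.microsecond / 1e6) / 86400.0
    )
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return int(365.25 * (y + 4716)) + int(30.6001 * (m + 1)) + d + b - 1524.5


def _sun_ephemeris(jc: float) -> tuple[float, float]:
    """Return (declination deg, equation of time min) at Julian century ``jc``."""
    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mrad = np.radians(m)
    c = (
        np.sin(mrad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * mrad) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = np.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)
    e0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = e0 + 0.00256 * np.cos(omega)
    obliq_rad = np.radians(obliq)
    decl = np.degrees(np.arcsin(np.sin(obliq_rad) * np.sin(np.radians(app_long))))
    y = np.tan(obliq_rad / 2.0) ** 2
    l0r = np.radians(l0)
    eot = 4.0 * np.degrees(
        y * np.sin(2 * l0r)
        - 2.0 * ecc * np.sin(mrad)
        + 4.0 * ecc * y * np.sin(mrad) * np.cos(2 * l0r)
        - 0.5 * y * y * np.sin(4 * l0r)
        - 1.25 * ecc * ecc * np.sin(2 * mrad)
    )
    return float(decl), float(eot)


def solar_elevation(lat: float, lon: float, t_local: datetime, tz_offset: float) -> float:
    """Solar elevation angle (degrees) at a local clock time.

    Parameters
    ----------
    lat, lon : float
        Site coordinates, degrees north / east (WGS84).
    t_local : datetime
        Naive local clock time.
    tz_offset : float
        Hours east of UTC for the local clock.
    """
    t_utc = t_local - timedelta(hours=tz_offset)
    jc = (_julian_day(t_utc) - 2451545.0) / 36525.0
    decl, eot = _sun_ephemeris(jc)
    minutes_local = t_local.hour * 60.0 + t_local.minute + t_local.second / 60.0
    tst = (minutes_local + eot + 4.0 * lon - 60.0 * tz_offset) % 1440.0
    ha = tst / 4.0 - 180.0
    lat_r, decl_r, ha_r = np.radians(lat), np.radians(decl), np.radians(ha)
    sin_elev = np.sin(lat_r) * np.sin(decl_r) + np.cos(lat_r) * np.cos(decl_r) * np.cos(ha_r)
    return float(np.degrees(np.arcsin(np.clip(sin_elev, -1.0, 1.0))))


def _events_once(lat: float, lon: float, day: _date, tz_offset: float, jc: float):
    decl, eot = _sun_ephemeris(jc)
    lat_r, decl_r = np.radians(lat), np.radians(decl)
    zenith = np.radians(90.0 - RISE_SET_ELEVATION)
    cos_ha = np.cos(zenith) / (np.cos(lat_r) * np.cos(decl_r)) - np.tan(lat_r) * np.tan(decl_r)
    if cos_ha < -1.0 or cos_ha > 1.0:
        kind = "polar day (sun never sets)" if cos_ha < -1.0 else "polar night (sun never rises)"
        raise NoSunEventError(f"no sunrise/sunset at lat={lat} on {day}: {kind}")
    ha_deg = np.degrees(np.arccos(cos_ha))
    noon_min = 720.0 - 4.0 * lon - eot + tz_offset * 60.0
    return noon_min - 4.0 * ha_deg, noon_min + 4.0 * ha_deg


def solar_events(lat: float, lon: float, day: _date | str, tz_offset: float) -> SolarDay:
    """Sunrise and sunset for one date at a site, in local clock time.

    Raises
    ------
    NoSunEventError
        If the sun does not cross the -0.833 degree horizon that date
        (polar day or polar night).  Never silently substitutes a default.
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    if not -180.0 <= lon <= 180.0:
        raise ValueError(f"longitude {lon} outside [-180, 180]")
    if isinstance(day, str):
        day = _date.fromisoformat(day)
    midnight = datetime(day.year, day.month, day.day)

    # first pass at local noon, then refine ephemeris at each event time
    jc_noon = (_julian_day(midnight + timedelta(hours=12 - tz_offset)) - 2451545.0) / 36525.0
    rise_min, set_min = _events_once(lat, lon, day, tz_offset, jc_noon)
    jc_rise = (_julian_day(midnight + timedelta(minutes=rise_min, hours=-tz_offset)) - 2451545.0) / 36525.0
    jc_set = (_julian_day(midnight + timedelta(minutes=set_min, hours=-tz_offset)) - 2451545.0) / 36525.0
    rise_min, _ = _events_once(lat, lon, day, tz_offset, jc_rise)
    _, set_min = _events_once(lat, lon, day, tz_offset, jc_set)

    sunrise = pd.Timestamp(midnight) + pd.Timedelta(minutes=rise_min)
    sunset = pd.Timestamp(midnight) + pd.Timedelta(minutes=set_min)
    return SolarDay(date=day, sunrise=sunrise.round("s"), sunset=sunset.round("s"))


def solar_table(
    lat: float, lon: float, start: _date | str, end: _date | str, tz_offset: float
) -> pd.DataFrame:
    """Table of SolarDay rows for every date in ``[start, end]`` inclusive.

    Columns: ``date`` (datetime.date), ``sunrise``, ``sunset`` (local Timestamps).
    """
    if isinstance(start, str):
        start = _date.fromisoformat(start)
    if isinstance(end, str):
        end = _date.fromisoformat(end)
    if end < start:
        raise ValueError(f"empty date range: {start} .. {end}")
    rows = []
    day = start
    while day <= end:
        ev = solar_events(lat, lon, day, tz_offset)
        rows.append((ev.date, ev.sunrise, ev.sunset))
        day = day + timedelta(days=1)
    return pd.DataFrame(rows, columns=["date", "sunrise", "sunset"])


def _check_solar(solar: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not {"date", "sunrise", "sunset"} <= set(solar.columns):
        raise ValueError("solar table needs columns: date, sunrise, sunset")
    s = solar.sort_values("sunrise")
    return (
        s["date"].to_numpy(),
        s["sunrise"].to_numpy(dtype="datetime64[ns]"),
        s["sunset"].to_numpy(dtype="datetime64[ns]"),
    )


def assign_bio_day(t, solar: pd.DataFrame) -> np.ndarray:
    """Map timestamps to their sunrise-anchored biological day.

    ``bio_day`` is the calendar date ``d`` with ``sunrise(d) <= t < sunrise(d+1)``
    (half-open on the right).  The solar table must cover every timestamp:
    each ``t`` must lie at/after the first sunrise and strictly before the
    last sunrise listed.

    Accepts a scalar, Series or array of timestamps; returns an array of
    ``datetime.date`` (or a scalar date for scalar input).
    """
    dates, sunrises, _ = _check_solar(solar)
    scalar = np.isscalar(t) or isinstance(t, (pd.Timestamp, datetime, str))
    tt = pd.to_datetime(pd.Series([t] if scalar else t)).to_numpy(dtype="datetime64[ns]")
    idx = np.searchsorted(sunrises, tt, side="right") - 1
    bad = (idx < 0) | (idx >= len(sunrises) - 1)
    if bad.any():
        missing = pd.to_datetime(tt[bad][:5]).astype(str).tolist()
        raise ValueError(
            f"{int(bad.sum())} timestamp(s) outside solar coverage "
            f"[{pd.Timestamp(sunrises[0])} .. {pd.Timestamp(sunrises[-1])}), e.g. {missing}"
        )
    out = dates[idx]
    return out[0] if scalar else out


def day_night(t, solar: pd.DataFrame) -> np.ndarray:
    """Classify timestamps as ``"day"`` (sunrise<=t<sunset) or ``"night"``.

    The phase is evaluated within each timestamp's own biological day, so
    everything from sunset up to (excluding) the next sunrise is night.
    """
    dates, sunrises, sunsets = _check_solar(solar)
    scalar = np.isscalar(t) or isinstance(t, (pd.Timestamp, datetime, str))
    tt = pd.to_datetime(pd.Series([t] if scalar else t)).to_numpy(dtype="datetime64[ns]")
    idx = np.searchsorted(sunrises, tt, side="right") - 1
    bad = (idx < 0) | (idx >= len(sunrises) - 1)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} timestamp(s) outside solar coverage")
    is_day = tt < sunsets[idx]  # t >= sunrise(idx) holds by construction
    out = np.where(is_day, "day", "night")
    return out[0] if scalar else out
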