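"""Synthetic accelerometer, weather and GPS data with known structure.

The generator emulates a summer biologging campaign on a nocturnal ungulate:

* hourly site weather — a seasonal mean temperature curve plus a diel
  sinusoid peaking mid-afternoon, day-level AR(1) anomalies that produce
  occasional multi-day warm runs, optional additive heatwave injections,
  and precipitation with a configurable dry-day probability (default 0.42);
* hourly activity (VeDBA-sum scale) — a smooth diel profile with dusk/dawn
  acrophases and a nocturnal plateau, a multiplicative temperature effect
  active only in dry hours, a seasonal day-of-year trend, log-normal
  individual random intercepts and log-normal residual noise;
* short full-rate 10 Hz triaxial streams — a slowly rotating gravity vector
  plus band-limited (1-3 Hz) dynamic bursts under Hann envelopes whose
  per-hour energy is calibrated to the hourly activity model;
* GPS fixes — a biased correlated random walk around a home-range centre
  with a configurable fraction of poor-DOP fixes.

Two fidelity levels are deliberate: full 10 Hz streams are only practical
for spans of about a week (a whole season would be ~80 M samples/animal),
so season-scale model tests consume the hourly-VeDBA generator directly.
Intended (noise-free) hourly intensities are always emitted alongside as a
ground-truth sidecar, so recovery tests never reach into generator internals.

The *nocturnal multiplier* is defined operationally: it is the ratio of the
mean hourly intensity over the night window 22:00-04:00 to the mean over
the day window 05:00-21:00.  The night-weight and acrophase basis curves
are balanced within those two windows so the parameter equals that contrast
exactly by construction, whatever the acrophase amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

__all__ = [
    "TempParams",
    "PrecipParams",
    "ActivityParams",
    "GpsParams",
    "SimConfig",
    "diel_profile",
    "gen_weather",
    "gen_hourly_vedba",
    "gen_accel",
    "gen_gps",
]

NIGHT_HOURS = (22, 23, 0, 1, 2, 3)
DAY_HOURS = tuple(range(5, 22))


@dataclass
class TempParams:
    """Seasonal + diel temperature model, degrees Celsius."""

    seasonal_mean: float = 19.6  # summer mean for the study region
    seasonal_amp: float = 2.0  # slow seasonal modulation, peaks ~DOY 200
    seasonal_peak_doy: float = 200.0
    diel_amp: float = 5.0  # half-range of the day cycle, max 15:00
    # day-level anomaly sd chosen so simulated summers span roughly 8-37 C,
    # the hourly range reported for the emulated study region
    ar1_sd: float = 4.0
    ar1_phi: float = 0.75
    # additive day-level boosts: (start_day_index, length_days, boost_c)
    heatwave_injection: list = field(default_factory=list)


@dataclass
class PrecipParams:
    dry_day_prob: float = 0.42
    wet_hour_rate: float = 0.25  # P(hour wet | day wet)
    rain_mm_shape: float = 0.6  # gamma shape of hourly depth on wet hours
    rain_mm_scale: float = 2.0


@dataclass
class ActivityParams:
    """Hourly activity model on the VeDBA-sum scale (arbitrary g-based units)."""

    baseline: float = 1000.0  # day-window mean intensity
    nocturnal_multiplier: float = 1.6  # night(22-04) / day(05-21) window contrast
    dawn_amp: float = 0.35  # acrophase bump heights, fraction of baseline
    dusk_amp: float = 0.45
    dawn_hour: float = 4.0
    dusk_hour: float = 21.5
    acro_width_h: float = 1.2
    temp_slope_dry: float = -0.03  # log-scale, per degree C, dry hours only
    temp_slope_wet: float = 0.0
    temp_ref_c: float = 20.0
    doy_trend: float = -0.002  # log-scale, per day (~ -17% across a summer)
    doy_ref: float = 182.0
    indiv_sd: float = 0.15  # log-scale sd of animal intercepts
    resid_sd: float = 0.15  # log-scale sd of hourly residuals


@dataclass
class GpsParams:
    centre_lat: float = 49.96
    centre_lon: float = 14.78
    step_scale_m: float = 150.0
    fix_interval_min: int = 30
    dop_out_frac: float = 0.15  # fraction of fixes with DOP outside [1, 7]
    walk_persistence: float = 0.5
    homing: float = 0.05


@dataclass
class SimConfig:
    """Full configuration of one synthetic campaign."""

    seed: int = 0
    n_animals: int = 5
    start: str = "2019-06-01"
    end: str = "2019-08-31"
    site_lat: float = 50.0
    site_lon: float = 14.8
    tz_offset: float = 2.0
    temp: TempParams = field(default_factory=TempParams)
    precip: PrecipParams = field(default_factory=PrecipParams)
    activity: ActivityParams = field(default_factory=ActivityParams)
    gps: GpsParams = field(default_factory=GpsParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.precip.dry_day_prob <= 1.0:
            raise ValueError("dry_day_prob must be in [0, 1]")
        for name, v in [
            ("ar1_sd", self.temp.ar1_sd),
            ("indiv_sd", self.activity.indiv_sd),
            ("resid_sd", self.activity.resid_sd),
        ]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if _date.fromisoformat(self.end) < _date.fromisoformat(self.start):
            raise ValueError(f"empty date range: {self.start} .. {self.end}")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")

    def animal_ids(self) -> list[str]:
        return [f"A{i + 1:02d}" for i in range(self.n_animals)]


def _rng(config: SimConfig, tag: int) -> np.random.Generator:
    # one independent, reproducible stream per generator component
    return np.random.default_rng([config.seed, tag])


def _circ_dist(h: np.ndarray, centre: float) -> np.ndarray:
    d = np.abs(h - centre)
    return np.minimum(d, 24.0 - d)


def diel_profile(p: ActivityParams) -> np.ndarray:
    """Relative intensity at integer hours 0..23.

    The profile is 1 + (m-1)*nu(h) + dawn/dusk bumps, where nu is a smooth
    circular night weight normalised to mean 0 over 05:00-21:00 and mean 1
    over 22:00-04:00, and each acrophase bump is projected to have zero mean
    in *both* windows.  Hence mean over the day window is exactly 1 and over
    the night window exactly the nocturnal multiplier.
    """
    h = np.arange(24.0)
    a_idx, b_idx = list(DAY_HOURS), list(NIGHT_HOURS)

    nu0 = np.exp(-_circ_dist(h, 0.5) ** 2 / (2 * 3.0**2))
    nu = (nu0 - nu0[a_idx].mean()) / (nu0[b_idx].mean() - nu0[a_idx].mean())

    def balanced_bump(centre: float) -> np.ndarray:
        g = np.exp(-_circ_dist(h, centre) ** 2 / (2 * p.acro_width_h**2))
        return g - g[a_idx].mean() - (g[b_idx].mean() - g[a_idx].mean()) * nu

    prof = (
        1.0
        + (p.nocturnal_multiplier - 1.0) * nu
        + p.dawn_amp * balanced_bump(p.dawn_hour)
        + p.dusk_amp * balanced_bump(p.dusk_hour)
    )
    if prof.min() <= 0:
        raise ValueError("diel profile not positive; reduce acrophase amplitudes")
    return prof


# ---------------------------------------------------------------- weather


def gen_weather(config: SimConfig) -> pd.DataFrame:
    """Hourly weather table: columns ``t`` (local naive), ``temp``, ``precip``.

    Deterministic given the seed.  With all noise sds at zero and no
    injections the temperature is exactly the seasonal + diel curve.
    """
    rng = _rng(config, 1)
    tp, pp = config.temp, config.precip
    days = config.dates
    n_days = len(days)
    hours = pd.date_range(days[0], days[-1] + pd.Timedelta(hours=23), freq="h")
    doy = hours.dayofyear.to_numpy(dtype=float)
    hod = hours.hour.to_numpy(dtype=float)

    seasonal = tp.seasonal_mean + tp.seasonal_amp * np.cos(
        2 * np.pi * (doy - tp.seasonal_peak_doy) / 365.0
    )
    diel = tp.diel_amp * np.cos(2 * np.pi * (hod - 15.0) / 24.0)

    z = rng.standard_normal(n_days)
    anom = np.empty(n_days)
    anom[0] = z[0]
    innov_sd = np.sqrt(1.0 - tp.ar1_phi**2)
    for d in range(1, n_days):
        anom[d] = tp.ar1_phi * anom[d - 1] + innov_sd * z[d]
    anom *= tp.ar1_sd

    boost = np.zeros(n_days)
    for start_day, length, b in tp.heatwave_injection:
        boost[start_day : start_day + length] += b

    day_index = np.repeat(np.arange(n_days), 24)[: len(hours)]
    temp = seasonal + diel + anom[day_index] + boost[day_index]

    wet_day = rng.random(n_days) >= pp.dry_day_prob
    wet_hour = rng.random(len(hours)) < pp.wet_hour_rate
    depth = rng.gamma(pp.rain_mm_shape, pp.rain_mm_scale, size=len(hours))
    precip = np.where(wet_day[day_index] & wet_hour, depth, 0.0)

    return pd.DataFrame({"t": hours, "temp": temp, "precip": precip})


# ------------------------------------------------------- hourly activity


def _animal_intercepts(config: SimConfig) -> np.ndarray:
    # shared between the hourly and 10 Hz generators so intercepts agree
    return _rng(config, 5).normal(0.0, config.activity.indiv_sd, size=config.n_animals)


def _hourly_intensity(config: SimConfig, weather: pd.DataFrame) -> pd.DataFrame:
    """Noise-free per-hour intensity shared by both fidelity levels."""
    ap = config.activity
    prof = diel_profile(ap)
    hod = pd.DatetimeIndex(weather["t"]).hour.to_numpy()
    doy = pd.DatetimeIndex(weather["t"]).dayofyear.to_numpy(dtype=float)
    temp = weather["temp"].to_numpy(dtype=float)
    wet = weather["precip"].to_numpy(dtype=float) > 0.0
    slope = np.where(wet, ap.temp_slope_wet, ap.temp_slope_dry)
    base = (
        ap.baseline
        * prof[hod]
        * np.exp(slope * (temp - ap.temp_ref_c))
        * np.exp(ap.doy_trend * (doy - ap.doy_ref))
    )
    return pd.DataFrame({"t": weather["t"].to_numpy(), "intensity": base})


def gen_hourly_vedba(config: SimConfig, weather: pd.DataFrame) -> pd.DataFrame:
    """Season-scale hourly activity for every animal (hourly fidelity level).

    Columns: ``animal_id``, ``t`` (hour start, local), ``vedba_sum`` (noisy
    observation) and ``vedba_true`` (the intended intensity including the
    animal intercept but excluding residual noise — the recovery-test truth).
    """
    rng = _rng(config, 4)
    ap = config.activity
    base = _hourly_intensity(config, weather)
    intercepts = _animal_intercepts(config)
    frames = []
    for i, aid in enumerate(config.animal_ids()):
        eps = rng.normal(0.0, ap.resid_sd, size=len(base))
        truth = base["intensity"].to_numpy() * np.exp(intercepts[i])
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": aid,
                    "t": base["t"].to_numpy(),
                    "vedba_sum": truth * np.exp(eps),
                    "vedba_true": truth,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ------------------------------------------------------------ 10 Hz accel

ACCEL_HZ = 10
_SAMPLES_PER_HOUR = 3600 * ACCEL_HZ


def gen_accel(
    config: SimConfig,
    weather: pd.DataFrame,
    animal_index: int = 0,
    days: int = 7,
    burst_s: float = 5.0,
    burst_coverage: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full-rate 10 Hz triaxial stream for one animal over ``days`` days.

    Returns ``(stream, truth)``: the stream has columns ``t, ax, ay, az``
    (g units); the truth sidecar has per-hour ``t, intensity`` — the target
    hourly VeDBA sum actually injected.

    Burst timing depends only on the seed, not on the animal, so two animals
    under the same seed differ purely by their intercept amplitude scaling.
    The per-hour dynamic energy is calibrated so that a perfect
    static/dynamic split would recover an hourly VeDBA sum equal to the
    intensity; rolling-mean static estimation attenuates this slightly, so
    downstream checks compare by rank, not level.
    """
    rng = _rng(config, 2)
    scale = float(np.exp(_animal_intercepts(config)[animal_index]))
    w = weather.iloc[: 24 * days]
    base = _hourly_intensity(config, w)
    n_hours = len(base)
    n = n_hours * _SAMPLES_PER_HOUR
    t0 = pd.Timestamp(w["t"].iloc[0])
    t = t0 + pd.to_timedelta(np.arange(n) * 100, unit="ms")

    # slowly rotating gravity orientation (~0.1 deg/s random walk)
    n_sec = n_hours * 3600
    dtheta = rng.normal(0.0, np.radians(0.1), size=n_sec)
    dphi = rng.normal(0.0, np.radians(0.1), size=n_sec)
    theta = np.repeat(np.cumsum(dtheta), ACCEL_HZ)
    phi = np.repeat(np.cumsum(dphi), ACCEL_HZ)
    gx = np.sin(theta) * np.cos(phi)
    gy = np.sin(theta) * np.sin(phi)
    gz = np.cos(theta)

    ax = gx.copy()
    ay = gy.copy()
    az = gz.copy()
    truth_intensity = np.zeros(n_hours)
    burst_len = int(burst_s * ACCEL_HZ)
    hann = np.hanning(burst_len)
    tt = np.arange(_SAMPLES_PER_HOUR) / ACCEL_HZ

    for hidx in range(n_hours):
        intensity = float(base["intensity"].iloc[hidx]) * scale
        truth_intensity[hidx] = intensity
        n_bursts = rng.poisson(burst_coverage * 3600.0 / burst_s)
        starts = rng.integers(0, _SAMPLES_PER_HOUR - burst_len, size=max(n_bursts, 0))
        freqs = rng.uniform(1.0, 3.0, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        if intensity <= 0 or n_bursts == 0:
            continue
        env = np.zeros(_SAMPLES_PER_HOUR)
        for s in starts:
            env[s : s + burst_len] += hann
        carriers = [np.sin(2 * np.pi * f * tt + p) for f, p in zip(freqs, phases)]
        norm = env * np.sqrt(sum(c**2 for c in carriers))
        total = norm.sum()
        if total <= 0:
            continue
        amp = intensity / total
        sl = slice(hidx * _SAMPLES_PER_HOUR, (hidx + 1) * _SAMPLES_PER_HOUR)
        ax[sl] += amp * env * carriers[0]
        ay[sl] += amp * env * carriers[1]
        az[sl] += amp * env * carriers[2]

    stream = pd.DataFrame({"t": t, "ax": ax, "ay": ay, "az": az})
    truth = pd.DataFrame({"t": base["t"].to_numpy(), "intensity": truth_intensity})
    return stream, truth


# ------------------------------------------------------------------- GPS


def gen_gps(config: SimConfig) -> pd.DataFrame:
    """Biased correlated random-walk GPS fixes for every animal.

    Columns: ``animal_id, t, lat, lon, dop``.  A configured fraction of
    fixes receives DOP outside [1, 7] (uniform on [0.5, 1) or (7, 10]) so
    the quality filter has known truth to remove.
    """
    rng = _rng(config, 3)
    gp = config.gps
    fixes_per_day = int(round(24 * 60 / gp.fix_interval_min))
    n_fix = len(config.dates) * fixes_per_day
    t = pd.date_range(
        config.dates[0], periods=n_fix, freq=pd.Timedelta(minutes=gp.fix_interval_min)
    )
    m_per_deg_lat = 111_320.0
    m_per_deg_lon = m_per_deg_lat * np.cos(np.radians(gp.centre_lat))

    frames = []
    for aid in config.animal_ids():
        steps = rng.normal(0.0, gp.step_scale_m, size=(n_fix, 2))
        pos = np.zeros((n_fix, 2))
        vel = np.zeros(2)
        for k in range(1, n_fix):
            vel = gp.walk_persistence * vel + steps[k]
            pos[k] = pos[k - 1] + vel - gp.homing * pos[k - 1]
        bad = rng.random(n_fix) < gp.dop_out_frac
        low = rng.random(n_fix) < 0.5
        dop = rng.uniform(1.0, 7.0, size=n_fix)
        dop = np.where(bad & low, rng.uniform(0.5, 1.0 - 1e-9, size=n_fix), dop)
        dop = np.where(bad & ~low, rng.uniform(7.0 + 1e-9, 10.0, size=n_fix), dop)
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": aid,
                    "t": t,
                    "lat": gp.centre_lat + pos[:, 1] / m_per_deg_lat,
                    "lon": gp.centre_lon + pos[:, 0] / m_per_deg_lon,
                    "dop": dop,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
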