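from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from boarheat import accel, simulate, solartime, weather

DATA = Path(__file__).parent / "data"

SITE = dict(lat=50.0, lon=14.8, tz=2.0)


@pytest.fixture(scope="session")
def solar_summer():
    """Solar table covering a padded June-September window at the study site."""
    return solartime.solar_table(SITE["lat"], SITE["lon"], "2019-05-31", "2019-09-02", SITE["tz"])


@pytest.fixture(scope="session")
def square_path():
    return pd.read_csv(DATA / "square_path.csv", parse_dates=["t"])


def make_gam1_table(seed=0, n_animals=5, start="2019-06-01", end="2019-07-30",
                    solar=None, activity=None, with_truth=False):
    """Simulated hourly modelling table (activity joined with hourly weather)."""
    cfg = simulate.SimConfig(
        seed=seed, n_animals=n_animals, start=start, end=end,
        activity=activity or simulate.ActivityParams(),
    )
    wx = simulate.gen_weather(cfg)
    act = simulate.gen_hourly_vedba(cfg, wx)
    wx_h = wx.copy()
    wx_h["precip_presence"] = weather.precip_binary(wx_h["precip"].to_numpy())
    tab = weather.join_weather(accel.hourly_from_simulated(act, solar), wx_h, on=["t_hour"])
    if with_truth:
        truth = act.rename(columns={"t": "t_hour"})[["animal_id", "t_hour", "vedba_true"]]
        tab = tab.merge(truth, on=["animal_id", "t_hour"])
    return tab


def make_gam2_table(seed=0, n_animals=5, start="2019-06-01", end="2019-08-31",
                    solar=None, activity=None):
    """Simulated daily modelling table (daily activity joined with daily weather)."""
    cfg = simulate.SimConfig(
        seed=seed, n_animals=n_animals, start=start, end=end,
        activity=activity or simulate.ActivityParams(),
    )
    wx = simulate.gen_weather(cfg)
    act = simulate.gen_hourly_vedba(cfg, wx)
    hourly = accel.hourly_from_simulated(act, solar)
    daily = accel.daily_summary(hourly)
    dwx = weather.daily_weather(wx, solar)
    return weather.join_weather(daily[daily["included"]], dwx, on=["bio_day"])


def sim_heatwave_table(rng, n_hw=30, n_an=10, beta_len_z=0.0, beta_len_precip_z=0.0,
                       sd_animal=1.0, sd_resid=1.0):
    """Heatwave-level dataset with known fixed effects on the z-covariate scale."""
    rows = []
    for h in range(n_hw):
        length = 1 + rng.poisson(1.0)
        tmax = rng.normal(26.0, 1.5)
        precip = int(rng.random() < 0.4)
        rows.append((h, length, tmax, precip))
    hw = pd.DataFrame(rows, columns=["heatwave_id", "length_days", "tmax_mean", "precip_presence"])
    lz = (hw["length_days"] - hw["length_days"].mean()) / max(hw["length_days"].std(ddof=0), 1e-9)
    b_an = rng.normal(0.0, sd_animal, n_an)
    out = []
    for a in range(n_an):
        d = hw.copy()
        d["animal_id"] = f"A{a:02d}"
        d["vedba_mean"] = (
            10.0
            + 0.5 * (d["tmax_mean"] - 26.0)
            + beta_len_z * lz
            + beta_len_precip_z * lz * d["precip_presence"]
            + b_an[a]
            + rng.normal(0.0, sd_resid, len(d))
        )
        out.append(d)
    return pd.concat(out, ignore_index=True)
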