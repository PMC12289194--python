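import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from boarheat import simulate
from boarheat.simulate import (
    ActivityParams,
    PrecipParams,
    SimConfig,
    TempParams,
    diel_profile,
    gen_gps,
    gen_hourly_vedba,
    gen_weather,
)


def test_noise_free_temperature_equals_seasonal_plus_diel_curve():
    tp = TempParams(ar1_sd=0.0)
    cfg = SimConfig(seed=0, start="2019-06-01", end="2019-06-05", temp=tp)
    wx = gen_weather(cfg)
    t = pd.DatetimeIndex(wx["t"])
    expected = (
        tp.seasonal_mean
        + tp.seasonal_amp * np.cos(2 * np.pi * (t.dayofyear - tp.seasonal_peak_doy) / 365.0)
        + tp.diel_amp * np.cos(2 * np.pi * (t.hour - 15.0) / 24.0)
    )
    np.testing.assert_allclose(wx["temp"].to_numpy(), expected, rtol=0, atol=1e-12)


def test_dry_day_probability_one_means_no_rain():
    cfg = SimConfig(seed=0, start="2019-06-01", end="2019-08-31",
                    precip=PrecipParams(dry_day_prob=1.0))
    assert (gen_weather(cfg)["precip"] == 0).all()


def test_dry_day_fraction_converges_to_configured_probability():
    # 10,000 simulated days; binomial sd of the dry fraction is ~0.005
    cfg = SimConfig(seed=11, start="1990-01-01", end="2017-05-18")
    wx = gen_weather(cfg)
    totals = wx.groupby(pd.DatetimeIndex(wx["t"]).date)["precip"].sum()
    assert len(totals) == 10000
    dry_frac = (totals == 0).mean()
    assert abs(dry_frac - 0.42) < 0.02


def test_same_seed_bit_identical_distinct_seeds_differ():
    a = gen_weather(SimConfig(seed=5, start="2019-06-01", end="2019-06-20"))
    b = gen_weather(SimConfig(seed=5, start="2019-06-01", end="2019-06-20"))
    c = gen_weather(SimConfig(seed=6, start="2019-06-01", end="2019-06-20"))
    pdt.assert_frame_equal(a, b)
    assert not a["temp"].equals(c["temp"])
    g1 = gen_gps(SimConfig(seed=5, start="2019-06-01", end="2019-06-03"))
    g2 = gen_gps(SimConfig(seed=5, start="2019-06-01", end="2019-06-03"))
    pdt.assert_frame_equal(g1, g2)


def test_empty_date_range_rejected():
    with pytest.raises(ValueError, match="empty date range"):
        SimConfig(seed=0, start="2019-08-31", end="2019-06-01")


def test_diel_profile_window_contrast_equals_multiplier():
    for m in (1.0, 1.3, 1.6, 2.0):
        prof = diel_profile(ActivityParams(nocturnal_multiplier=m))
        day = prof[list(simulate.DAY_HOURS)].mean()
        night = prof[list(simulate.NIGHT_HOURS)].mean()
        assert day == pytest.approx(1.0, abs=1e-12)
        assert night / day == pytest.approx(m, abs=1e-12)


def test_flat_profile_when_no_acrophases_and_unit_multiplier():
    prof = diel_profile(ActivityParams(nocturnal_multiplier=1.0, dawn_amp=0.0, dusk_amp=0.0))
    assert prof.max() / prof.min() < 1.05


def test_heatwave_injection_boosts_exactly_those_days():
    base = SimConfig(seed=0, start="2019-06-01", end="2019-06-20", temp=TempParams(ar1_sd=0.0))
    boosted = SimConfig(
        seed=0, start="2019-06-01", end="2019-06-20",
        temp=TempParams(ar1_sd=0.0, heatwave_injection=[(5, 3, 7.0)]),
    )
    d = gen_weather(boosted)["temp"] - gen_weather(base)["temp"]
    per_day = d.groupby(np.arange(len(d)) // 24).mean()
    assert (per_day.iloc[5:8] == 7.0).all()
    assert (per_day.drop(index=[5, 6, 7]) == 0.0).all()


def test_gps_stationary_when_step_scale_zero():
    cfg = SimConfig(seed=0, n_animals=1, start="2019-06-01", end="2019-06-03",
                    gps=simulate.GpsParams(step_scale_m=0.0))
    g = gen_gps(cfg)
    assert (g["lat"] == cfg.gps.centre_lat).all()
    assert (g["lon"] == cfg.gps.centre_lon).all()


def test_gps_dop_outlier_fraction_matches_configuration():
    cfg = SimConfig(seed=3, n_animals=1, start="2019-06-01", end="2019-08-31",
                    gps=simulate.GpsParams(dop_out_frac=0.2))
    g = gen_gps(cfg)
    assert len(g) >= 4000
    bad = ((g["dop"] < 1.0) | (g["dop"] > 7.0)).mean()
    # binomial 99% CI half-width at n~4400 is ~0.016
    assert abs(bad - 0.2) < 0.02


def test_hourly_vedba_truth_is_noise_free_intensity():
    ap = ActivityParams(resid_sd=0.0)
    cfg = SimConfig(seed=2, n_animals=2, start="2019-06-01", end="2019-06-10", activity=ap)
    wx = gen_weather(cfg)
    hv = gen_hourly_vedba(cfg, wx)
    np.testing.assert_allclose(hv["vedba_sum"], hv["vedba_true"], rtol=1e-12)


def test_accel_zero_intensity_gives_near_zero_vedba():
    from boarheat import accel

    ap = ActivityParams(baseline=0.0)
    cfg = SimConfig(seed=1, n_animals=1, start="2019-06-01", end="2019-06-01", activity=ap)
    wx = gen_weather(cfg)
    stream, truth = simulate.gen_accel(cfg, wx, days=1)
    assert (truth["intensity"] == 0).all()
    v = accel.vedba(stream)
    # residual VeDBA from the slowly rotating gravity vector only
    assert v["vedba"].max() < 0.01


def test_accel_same_seed_same_burst_timing_scaled_amplitude():
    from boarheat import accel

    ap = ActivityParams(indiv_sd=0.5)
    cfg = SimConfig(seed=4, n_animals=2, start="2019-06-01", end="2019-06-01", activity=ap)
    wx = gen_weather(cfg)
    s0, t0 = simulate.gen_accel(cfg, wx, animal_index=0, days=1)
    s1, t1 = simulate.gen_accel(cfg, wx, animal_index=1, days=1)
    ratio = t1["intensity"] / t0["intensity"]
    np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)
    v0 = accel.vedba(s0)["vedba"].to_numpy()
    v1 = accel.vedba(s1)["vedba"].to_numpy()
    active = v0 > 0.05
    assert active.any()
    np.testing.assert_allclose(
        np.median(v1[active] / v0[active]), float(ratio.iloc[0]), rtol=0.05
    )


def test_accel_hourly_vedba_tracks_intended_intensity(solar_summer):
    """End-to-end self-consistency: hourly VeDBA sums rank-match the truth sidecar."""
    from scipy.stats import spearmanr

    from boarheat import accel

    cfg = SimConfig(seed=1, n_animals=1, start="2019-06-01", end="2019-06-07")
    wx = gen_weather(cfg)
    stream, truth = simulate.gen_accel(cfg, wx, days=7)
    v = accel.vedba(stream)
    hourly = accel.hourly_summary(v, solar_summer)
    joined = hourly[hourly["complete"]].merge(
        truth.rename(columns={"t": "t_hour"}), on="t_hour"
    )
    rho = spearmanr(joined["vedba_sum"], joined["intensity"]).statistic
    assert rho > 0.95
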