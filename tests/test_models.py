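import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from boarheat import models, simulate
from conftest import make_gam1_table, make_gam2_table, sim_heatwave_table


def quiet_activity(**kw):
    defaults = dict(indiv_sd=0.0, resid_sd=0.0, doy_trend=0.0)
    defaults.update(kw)
    return simulate.ActivityParams(**defaults)


@pytest.fixture(scope="module")
def gam1_fit(solar_summer):
    tab = make_gam1_table(seed=7, solar=solar_summer)
    return models.fit_gam_hourly(tab), tab


def test_cyclic_hour_prediction_periodic(gam1_fit):
    fit, _ = gam1_fit
    for precip in (0, 1):
        g0 = pd.DataFrame({"clock_hour": [0.0], "temp": [20.0], "precip_presence": [precip]})
        g24 = pd.DataFrame({"clock_hour": [24.0], "temp": [20.0], "precip_presence": [precip]})
        assert fit.predict(g0)[0] == pytest.approx(fit.predict(g24)[0], abs=1e-8)


def test_constant_response_gives_flat_fit():
    rng = np.random.default_rng(0)
    tab = pd.DataFrame(
        {
            "vedba_daily_mean": 500.0,
            "temp_max": rng.uniform(18, 32, 200),
            "doy": np.tile(np.arange(152, 252), 2)[:200],
            "precip_presence": rng.integers(0, 2, 200),
            "animal_id": np.tile(["A", "B"], 100),
        }
    )
    fit = models.fit_gam_seasonal(tab)
    pred = fit.predict(tab)
    np.testing.assert_allclose(pred, 500.0, rtol=1e-6)


def test_response_shift_equivariance(solar_summer):
    tab = make_gam1_table(seed=1, n_animals=3, end="2019-06-30", solar=solar_summer)
    shifted = tab.assign(vedba_sum=tab["vedba_sum"] + 5000.0)
    f1 = models.fit_gam_hourly(tab)
    f2 = models.fit_gam_hourly(shifted)
    grid = pd.DataFrame({"clock_hour": range(24), "temp": 20.0, "precip_presence": 0})
    np.testing.assert_allclose(f2.predict(grid) - f1.predict(grid), 5000.0, rtol=1e-4)
    # smooth shapes unchanged: hour-term effects agree
    name = "s(clock_hour,cc,precip_presence=0)"
    np.testing.assert_allclose(
        f1.term_effect(name, grid), f2.term_effect(name, grid), atol=1e-3
    )


def test_noise_free_limit_reproduces_generating_curve(solar_summer):
    tab = make_gam1_table(
        seed=3, n_animals=2, solar=solar_summer, activity=quiet_activity(), with_truth=True
    )
    fit = models.fit_gam_hourly(tab, k_tensor=8)
    pred = fit.predict(tab)
    rel_rms = np.sqrt(np.mean((pred - tab["vedba_true"]) ** 2)) / tab["vedba_true"].mean()
    assert rel_rms < 0.01


def test_single_precip_level_collapses_with_warning(solar_summer):
    tab = make_gam1_table(seed=1, n_animals=2, end="2019-06-20", solar=solar_summer)
    tab = tab[tab["precip_presence"] == 0]
    with pytest.warns(UserWarning, match="one level"):
        fit = models.fit_gam_hourly(tab)
    assert "precip_presence" not in fit.edf_by_term


def test_percent_change_zero_for_flat_profile(solar_summer):
    flat = quiet_activity(nocturnal_multiplier=1.0, dawn_amp=0.0, dusk_amp=0.0,
                          temp_slope_dry=0.0, temp_slope_wet=0.0)
    tab = make_gam1_table(seed=2, n_animals=2, end="2019-06-30", solar=solar_summer, activity=flat)
    fit = models.fit_gam_hourly(tab)
    pc = models.percent_change(fit, (16, 17, 18), (20, 21, 22), temp=20.0, precip=0)
    assert abs(pc) < 2.0
    assert abs(models.night_day_elevation(fit)) < 2.0


def test_percent_change_recovers_known_window_ratio(solar_summer):
    tab = make_gam1_table(seed=3, n_animals=2, solar=solar_summer, activity=quiet_activity())
    fit = models.fit_gam_hourly(tab, k_tensor=8)
    prof = simulate.diel_profile(simulate.ActivityParams())
    truth = 100.0 * (prof[[20, 21, 22]].mean() / prof[[16, 17, 18]].mean() - 1.0)
    rec = models.percent_change(fit, (16, 17, 18), (20, 21, 22), temp=20.0, precip=0)
    assert rec == pytest.approx(truth, abs=5.0)


def test_percent_change_undefined_for_nonpositive_baseline(gam1_fit, solar_summer):
    # a negated response makes every window mean negative: contrast undefined
    tab = make_gam1_table(seed=1, n_animals=2, end="2019-06-20", solar=solar_summer)
    fit = models.fit_gam_hourly(tab.assign(vedba_sum=-tab["vedba_sum"]))
    with pytest.raises(ValueError, match="undefined"):
        models.percent_change(fit, (12,), (20,), temp=20.0, precip=0)


def test_night_day_elevation_matches_truth_window_means(solar_summer):
    """With unit multiplier and acrophases only, contrast sign/magnitude match truth."""
    ap = quiet_activity(nocturnal_multiplier=1.0)
    tab = make_gam1_table(seed=5, n_animals=2, solar=solar_summer, activity=ap)
    # hour basis rich enough to resolve the narrow acrophase bumps exactly
    fit = models.fit_gam_hourly(tab, k=16, k_tensor=8)
    prof = simulate.diel_profile(simulate.ActivityParams(nocturnal_multiplier=1.0))
    truth = 100.0 * (
        prof[list(models.NIGHT_WINDOW)].mean() / prof[list(models.DAY_WINDOW)].mean() - 1.0
    )
    assert truth == pytest.approx(0.0, abs=1e-9)  # window-balanced by construction
    assert models.night_day_elevation(fit) == pytest.approx(truth, abs=3.0)


def test_seasonal_constant_and_declining_trend(solar_summer):
    tab = make_gam2_table(seed=2, solar=solar_summer)
    fit = models.fit_gam_seasonal(tab)
    cur = models.doy_response_curve(fit)
    assert cur["pred"].iloc[-1] < cur["pred"].iloc[0]  # simulated decline recovered


def test_seasonal_movement_response_increasing_trend(solar_summer):
    # daily distance rising over the season: the DOY effect should rise too
    rng = np.random.default_rng(0)
    n_days = 80
    days = pd.date_range("2019-06-01", periods=n_days)
    rows = []
    for aid in ("A", "B", "C"):
        base = rng.normal(4000, 200)
        rows.append(
            pd.DataFrame(
                {
                    "distance_m": base + 25.0 * np.arange(n_days) + rng.normal(0, 300, n_days),
                    "temp_max": rng.uniform(18, 32, n_days),
                    "doy": days.dayofyear,
                    "precip_presence": rng.integers(0, 2, n_days),
                    "animal_id": aid,
                }
            )
        )
    fit = models.fit_gam_seasonal(pd.concat(rows, ignore_index=True), response="distance_m")
    cur = models.doy_response_curve(fit)
    assert cur["pred"].iloc[-1] > cur["pred"].iloc[0]


def test_lmm_exact_recovery_in_deterministic_limit():
    rng = np.random.default_rng(0)
    df = sim_heatwave_table(rng, n_hw=20, n_an=4, sd_animal=0.0, sd_resid=0.0)
    lz = (df["length_days"] - df["length_days"].mean()) / df["length_days"].std(ddof=0)
    tz = (df["tmax_mean"] - df["tmax_mean"].mean()) / df["tmax_mean"].std(ddof=0)
    df["vedba_mean"] = 5.0 + 2.0 * tz - 1.5 * lz + 0.8 * df["precip_presence"]
    res = models.fit_lmm_heatwave(df)
    est = res.coef["estimate"]
    assert est["Intercept"] == pytest.approx(5.0, abs=1e-6)
    assert est["tmax_z"] == pytest.approx(2.0, abs=1e-6)
    assert est["length_z"] == pytest.approx(-1.5, abs=1e-6)
    assert est["precip"] == pytest.approx(0.8, abs=1e-6)


def test_lmm_rejects_inestimable_designs():
    rng = np.random.default_rng(1)
    df = sim_heatwave_table(rng, n_hw=10, n_an=4)
    with pytest.raises(ValueError, match="2 heatwaves"):
        models.fit_lmm_heatwave(df[df["heatwave_id"] == 0])
    with pytest.raises(ValueError, match="2 animals"):
        models.fit_lmm_heatwave(df[df["animal_id"] == "A00"])


def test_lmm_r2_decomposition_sane():
    rng = np.random.default_rng(2)
    res = models.fit_lmm_heatwave(sim_heatwave_table(rng))
    assert 0.0 <= res.r2_marginal <= res.r2_conditional <= 1.0


def test_temperature_smooth_type_one_error_controlled(solar_summer):
    """Null-simulation calibration of the approximate smooth-term test.

    Under a null temperature effect the dry-day temperature smooth should
    be flagged at nominal 0.05 no more than 10% of the time (the Wald
    approximation on the Bayesian covariance is conservative).
    """
    # doy_trend must also be zero: activity otherwise declines over the
    # season while temperature drifts with it, a real (not spurious) confound
    null = simulate.ActivityParams(temp_slope_dry=0.0, temp_slope_wet=0.0, doy_trend=0.0)
    rejections = 0
    reps = 40
    for seed in range(reps):
        tab = make_gam1_table(
            seed=seed, n_animals=2, end="2019-06-30", solar=solar_summer, activity=null
        )
        fit = models.fit_gam_hourly(tab)
        if fit.term_pvalues["s(temp,precip_presence=0)"] <= 0.05:
            rejections += 1
    assert rejections / reps <= 0.10
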