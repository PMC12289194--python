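import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boarheat import accel


def make_stream(values, hz=10.0, start="2019-06-02 12:00:00"):
    t = pd.Timestamp(start) + pd.to_timedelta(np.arange(len(values)) * (1000.0 / hz), unit="ms")
    v = np.asarray(values, dtype=float)
    return pd.DataFrame({"t": t, "ax": v[:, 0], "ay": v[:, 1], "az": v[:, 2]})


def brute_force_static(x, n):
    """Centred rolling mean with shrinking edges, one value at a time."""
    half = n // 2
    out = np.empty(len(x))
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = np.mean(x[lo:hi])
    return out


def brute_force_vedba(stream, n=21):
    axes = stream[["ax", "ay", "az"]].to_numpy()
    static = np.column_stack([brute_force_static(axes[:, j], n) for j in range(3)])
    v = np.sqrt(((axes - static) ** 2).sum(axis=1))
    return v, brute_force_static(v, n)


def test_constant_stream_static_equals_input_and_vedba_zero():
    s = make_stream(np.tile([0.0, 0.0, 1.0], (600, 1)))
    st_ = accel.static_component(s)
    np.testing.assert_array_equal(st_[["ax", "ay", "az"]].to_numpy(), s[["ax", "ay", "az"]].to_numpy())
    v = accel.vedba(s)
    assert (v["vedba"] == 0).all()
    assert (v["vedba_smoothed"] == 0).all()


def test_single_sample_static_is_that_sample():
    s = make_stream([[0.1, -0.2, 0.95]])
    out = accel.static_component(s)
    np.testing.assert_allclose(out[["ax", "ay", "az"]].to_numpy(), [[0.1, -0.2, 0.95]])


def test_non_monotonic_timestamps_rejected():
    s = make_stream(np.zeros((5, 3)))
    s.loc[3, "t"] = s.loc[1, "t"]
    with pytest.raises(ValueError, match="strictly increasing"):
        accel.static_component(s)


def test_static_matches_brute_force_on_sinusoid():
    x = np.sin(2 * np.pi * 1.0 * np.arange(600) / 10.0)
    s = make_stream(np.column_stack([x, np.zeros(600), np.ones(600)]))
    out = accel.static_component(s)
    np.testing.assert_allclose(out["ax"].to_numpy(), brute_force_static(x, 21), rtol=0, atol=1e-12)


def test_single_axis_spike_reduces_to_absolute_dynamic():
    vals = np.tile([0.0, 0.0, 1.0], (200, 1))
    vals[100, 0] = 0.5
    s = make_stream(vals)
    v = accel.vedba(s)
    st_ = accel.static_component(s)
    expected = abs(0.5 - st_["ax"].iloc[100])  # only ax has any dynamic part
    assert v["vedba"].iloc[100] == pytest.approx(expected, rel=1e-12)


def test_vedba_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    s = make_stream(rng.normal(0, 0.3, size=(600, 3)) + [0, 0, 1])
    out = accel.vedba(s)
    v, sm = brute_force_vedba(s)
    np.testing.assert_allclose(out["vedba"].to_numpy(), v, rtol=1e-9)
    np.testing.assert_allclose(out["vedba_smoothed"].to_numpy(), sm, rtol=1e-9)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    perm=st.permutations([0, 1, 2]),
    signs=st.tuples(*[st.sampled_from([-1.0, 1.0])] * 3),
    seed=st.integers(0, 100),
)
def test_vedba_invariant_under_axis_permutation_and_sign_flip(perm, signs, seed):
    rng = np.random.default_rng(seed)
    vals = rng.normal(0, 0.3, size=(100, 3))
    s1 = make_stream(vals)
    s2 = make_stream(vals[:, perm] * np.asarray(signs))
    np.testing.assert_allclose(
        accel.vedba(s1)["vedba"].to_numpy(), accel.vedba(s2)["vedba"].to_numpy(), atol=1e-12
    )


def test_added_disjoint_motion_never_decreases_vedba():
    # B's bursts are separated from A's by more than the smoothing window,
    # so adding them can only add dynamic signal at every sample
    n = 1200
    a = np.zeros((n, 3))
    a[:, 2] = 1.0
    a[100:150, 0] += 0.3 * np.sin(np.arange(50))
    b = np.zeros((n, 3))
    b[600:700, 1] += 0.4 * np.sin(np.arange(100) / 3)
    va = accel.vedba(make_stream(a))["vedba"].to_numpy()
    vab = accel.vedba(make_stream(a + b))["vedba"].to_numpy()
    assert (vab >= va - 1e-12).all()


def test_gap_breaks_smoothing_window():
    vals = np.tile([0.0, 0.0, 1.0], (40, 1))
    vals[:20, 0] = 0.5  # step change exactly at a 2 s recording gap
    s = make_stream(vals)
    s.loc[20:, "t"] = s.loc[20:, "t"] + pd.Timedelta(seconds=2)
    out = accel.static_component(s)
    # each segment is internally constant, so no smearing across the gap
    np.testing.assert_allclose(out["ax"].iloc[:20], 0.5)
    np.testing.assert_allclose(out["ax"].iloc[20:], 0.0)


def test_hourly_sum_closed_form_for_constant_series(solar_summer):
    t = pd.date_range("2019-06-02 06:00:00", periods=2 * 36000, freq="100ms")
    series = pd.DataFrame({"t": t, "vedba": 0.02, "vedba_smoothed": 0.02})
    out = accel.hourly_summary(series, solar_summer)
    complete = out[out["complete"]]
    assert len(complete) == 2
    np.testing.assert_allclose(complete["vedba_sum"], 36000 * 0.02, rtol=1e-9)
    np.testing.assert_allclose(complete["coverage"], 1.0)


def test_hourly_summary_empty_hours_absent(solar_summer):
    # two hours of data with a full silent hour between them
    t1 = pd.date_range("2019-06-02 06:00:00", periods=36000, freq="100ms")
    t2 = pd.date_range("2019-06-02 08:00:00", periods=36000, freq="100ms")
    series = pd.DataFrame({"t": t1.append(t2), "vedba": 0.1, "vedba_smoothed": 0.1})
    out = accel.hourly_summary(series, solar_summer)
    assert set(pd.DatetimeIndex(out["t_hour"]).hour) == {6, 8}


def test_hourly_sums_match_brute_force_groupby(solar_summer):
    rng = np.random.default_rng(7)
    t = pd.date_range("2019-06-02 03:00:00", periods=3 * 24 * 3600, freq="1s")  # 1 Hz, 3 days
    v = rng.exponential(0.05, len(t))
    series = pd.DataFrame({"t": t, "vedba": v, "vedba_smoothed": v})
    out = accel.hourly_summary(series, solar_summer, hz=1.0)

    # independent oracle: linear-scan bio-day assignment + dict accumulation
    sunrises = solar_summer.sort_values("sunrise")
    sr = sunrises["sunrise"].to_numpy()
    dates = sunrises["date"].to_numpy()
    acc = {}
    for ts, val in zip(t, v):
        ts64 = np.datetime64(ts)
        day = None
        for i in range(len(sr) - 1):
            if sr[i] <= ts64 < sr[i + 1]:
                day = dates[i]
                break
        key = (day, ts.floor("h"))
        acc[key] = acc.get(key, 0.0) + val
    assert len(out) == len(acc)
    for _, row in out.iterrows():
        assert row["vedba_sum"] == pytest.approx(acc[(row["bio_day"], row["t_hour"])], rel=1e-9)

    # conservation: total over hours equals total over samples
    assert out["vedba_sum"].sum() == pytest.approx(v.sum(), rel=1e-12)


def test_daily_mean_of_equal_hours_and_minimum_hour_rule():
    hourly = pd.DataFrame(
        {
            "animal_id": "A01",
            "bio_day": ["2019-06-02"] * 24 + ["2019-06-03"] * 10,
            "t_hour": pd.date_range("2019-06-02 05:00", periods=34, freq="h"),
            "clock_hour": 0,
            "vedba_sum": [50.0] * 24 + [80.0] * 10,
            "coverage": 1.0,
            "complete": True,
        }
    )
    out = accel.daily_summary(hourly, min_hours=20)
    full = out[out["bio_day"] == "2019-06-02"].iloc[0]
    short = out[out["bio_day"] == "2019-06-03"].iloc[0]
    assert full["vedba_daily_mean"] == pytest.approx(50.0)
    assert full["included"]
    assert not short["included"]


def test_daily_means_match_brute_force(solar_summer):
    from boarheat import simulate, weather  # noqa: F401

    cfg = simulate.SimConfig(seed=9, n_animals=2, start="2019-06-01", end="2019-06-20")
    wx = simulate.gen_weather(cfg)
    act = simulate.gen_hourly_vedba(cfg, wx)
    hourly = accel.hourly_from_simulated(act, solar_summer)
    out = accel.daily_summary(hourly)
    for _, row in out.iterrows():
        sub = hourly[(hourly["animal_id"] == row["animal_id"]) & (hourly["bio_day"] == row["bio_day"])]
        assert row["vedba_daily_mean"] == pytest.approx(sub["vedba_sum"].mean(), rel=1e-12)
        assert row["hours_present"] == len(sub)
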