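"""Fit the hourly and seasonal activity models and derive effect contrasts.

Simulates five animals over sixty summer days (hourly fidelity), joins
activity with hourly weather, fits the penalized additive mixed models and
prints the headline contrasts: the night-over-day activity elevation and
the late-afternoon-to-sunset activity increase at low and high temperature.
"""

from boarheat import accel, models, simulate, solartime, weather

cfg = simulate.SimConfig(seed=1, n_animals=5, start="2019-06-01", end="2019-07-30")
wx = simulate.gen_weather(cfg)
act = simulate.gen_hourly_vedba(cfg, wx)
solar = solartime.solar_table(50.0, 14.8, "2019-05-31", "2019-08-01", tz_offset=2.0)

hourly = accel.hourly_from_simulated(act, solar)
wx_h = wx.assign(precip_presence=weather.precip_binary(wx["precip"].to_numpy()))
gam1_table = weather.join_weather(hourly, wx_h, on=["t_hour"])

fit = models.fit_gam_hourly(gam1_table)
print(fit.summary())

elev = models.night_day_elevation(fit)
pc15 = models.percent_change(fit, (16, 17, 18), (20, 21, 22), temp=15.0, precip=0)
pc30 = models.percent_change(fit, (16, 17, 18), (20, 21, 22), temp=30.0, precip=0)
print(f"\nnight (22:00-04:00) vs day (05:00-21:00) activity elevation: {elev:+.1f}%")
print(f"late afternoon -> sunset increase at 15 C, dry: {pc15:+.1f}%")
print(f"late afternoon -> sunset increase at 30 C, dry: {pc30:+.1f}%")
print("(the generator injects a 1.6x nocturnal multiplier, so ~+60% is the truth;")
print(" the sunset contrast reflects the dusk acrophase of the diel profile)")

daily = accel.daily_summary(hourly)
dwx = weather.daily_weather(wx, solar)
gam2_table = weather.join_weather(daily[daily["included"]], dwx, on=["bio_day"])
fit2 = models.fit_gam_seasonal(gam2_table)
cur = models.doy_response_curve(fit2)
decline = 100.0 * (cur["pred"].iloc[-1] / cur["pred"].iloc[0] - 1.0)
print(f"\nseasonal model: fitted activity change across the study window: {decline:+.1f}%")
print("(the generator injects a declining day-of-year trend)")
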