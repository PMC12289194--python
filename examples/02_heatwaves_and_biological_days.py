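"""Detect heatwaves in a simulated summer on sunrise-anchored days.

Generates hourly site weather for June-August, aggregates it to biological
days (sunrise to next sunrise), and lists every maximal run of days whose
mean temperature exceeds the 24 degree C thermoneutral-zone threshold.
"""

from boarheat import heatwave, simulate, solartime, weather

cfg = simulate.SimConfig(seed=1)
wx = simulate.gen_weather(cfg)
print(f"hourly weather: {len(wx)} rows, temperature {wx['temp'].min():.1f}..{wx['temp'].max():.1f} C")

solar = solartime.solar_table(50.0, 14.8, "2019-05-31", "2019-09-01", tz_offset=2.0)
daily = weather.daily_weather(wx, solar)
dry_pct = 100.0 * (daily["precip_presence"] == 0).mean()
print(f"daily table: {len(daily)} biological days, {dry_pct:.0f}% without precipitation")

waves = heatwave.detect_heatwaves(daily, threshold_c=24.0, min_hours=23)
print(f"\n{len(waves)} heatwave(s) (mean daily temperature > 24 C):")
for w in waves:
    print(f"  {w.start_day} -> {w.end_day}  ({w.length_days} day(s))")
print("\nLengths are whole biological days; single-day events count as heatwaves.")
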