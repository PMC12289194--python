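# boarheat

Biologging analysis of how summer heat and rain reshape the activity of a
nocturnal ungulate (wild boar, *Sus scrofa*), built as a reusable, tested
Python pipeline.  The package covers the full chain from raw sensor
streams to fitted models:

* **VeDBA** — the vectorial sum of dynamic body acceleration, a proxy for
  movement-based energy expenditure, computed from 10 Hz triaxial
  accelerometer streams: per-axis static (gravitational) acceleration by a
  2 s centred rolling mean, `VeDBA = sqrt(sum_axis (raw - static)^2)`, then a
  second 2 s centred smoothing;
* **biological days** — sunrise-to-next-sunrise days (NOAA solar-position
  equations at -0.833 degrees elevation), so the single nocturnal active
  phase is never split at midnight;
* **weather** — hourly temperature and precipitation, with precipitation
  coded as a strict binary presence factor (> 0 mm) at every temporal
  scale, aggregated to biological days;
* **heatwaves** — maximal runs of consecutive days whose mean temperature
  exceeds 24 degrees C (the upper edge of the species' summer thermoneutral
  zone) with at least 23 h of data coverage;
* **GPS movement** — fixes filtered to DOP in [1, 7]; daily distance
  travelled, maximum net squared displacement and mean speed via the
  haversine formula (R = 6371 km);
* **models** —
  * hourly: `vedba_sum ~ s(temp, by=precip) + s(hour, cyclic, by=precip) +
    ti(temp, hour, by=precip) + precip + (1 | animal)`,
  * seasonal: `vedba_daily_mean ~ s(T_max, by=precip) + s(DOY, by=precip) +
    ti(T_max, DOY, by=precip) + precip + (1 | animal)` (also used post hoc
    with the movement metrics as responses),
  * heatwave: Gaussian LMM of period-mean VeDBA on z-scored mean daily
    maximum temperature and heatwave length, precipitation presence and
    both interactions, with an animal random intercept;

  the additive models are penalized regression splines (P-splines with
  cyclic and tensor-product interaction bases) with GCV-selected smoothing
  and a ridge-penalized animal intercept, fitted by this package's own
  engine; the mixed model uses statsmodels MixedLM with Nakagawa
  marginal/conditional R².

A first-class synthetic-data generator (`boarheat.simulate`) emulates the
whole campaign — nocturnal-dominant diel activity with dusk/dawn
acrophases, a negative temperature effect on dry hours only, seasonal
decline, individual variation, a summer temperature field with heatwave
runs, 42% dry days, and biased correlated random-walk GPS — with exact
ground-truth sidecars, so every downstream stage is testable without any
field data.

## Worked example

`examples/04_weather_activity_models.py` simulates 5 animals over 60 summer
days, fits the hourly model and prints (abridged):

```
Penalized additive mixed model: vedba_sum
n = 7200; adj R^2 = 0.834; deviance explained = 0.834

term                                   edf  p(approx)
precip_presence                       1.00     0.0000
s(temp,precip_presence=0)             1.82     0.0000
s(clock_hour,cc,precip_presence=0)   10.87     0.0000
ti(temp,clock_hour,precip_presence=0) 5.39     0.0000
...

night (22:00-04:00) vs day (05:00-21:00) activity elevation: +59.9%
late afternoon -> sunset increase at 15 C, dry: +66.7%
late afternoon -> sunset increase at 30 C, dry: +72.2%
seasonal model: fitted activity change across the study window: -16.2%
```

The generator injected a 1.6x nocturnal multiplier (truth: +60% elevation),
a dusk acrophase (truth: ~+71% sunset increase at fixed temperature) and a
declining day-of-year trend (truth: ~-17%), so the fitted contrasts recover
the generating process.  The dry-day temperature smooth is significantly
negative while the wet-day one is flat — the injected rain-dependent heat
response.

The other examples cover raw-stream VeDBA (`01`), heatwave detection on
biological days (`02`) and GPS movement metrics (`03`).  The end-to-end
pipeline, with stage-numbered artifact directories and a row-count
manifest, runs from a flat YAML config:

```bash
boarheat run --config examples/run_config.yaml --out-dir scratch/demo
```

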