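# Methods

This note documents the models, algorithms and design choices behind
`boarheat`, and what the simulation-based tests do and do not demonstrate.

## Signal processing: from raw acceleration to activity

Raw input is a 10 Hz triaxial stream in g (surge, heave, sway).  The
static, gravitational component of each axis is estimated by a centred
rolling mean over 2 s (21 samples; the nearest odd count), per-sample
VeDBA is the Euclidean norm of the residual dynamic components, and the
"smoothed VeDBA" is a second 2 s centred rolling mean of that norm.  Two
edge policies matter:

* window edges shrink rather than dropping samples, so hour boundaries
  lose no data and the hourly sums conserve the total signal;
* rolling windows never bridge recording gaps longer than 1 s, so a
  dropout cannot smear activity across its edges.

Smoothing the norm *after* the static/dynamic split is the conventional
tag-software reading of a "smoothed VeDBA" export; both window lengths are
arguments if a different convention is needed.  Units stay in g
throughout; hourly sums are therefore in g-samples (36,000 samples/hour at
full coverage).

Hourly sums are labelled with the *biological day* — sunrise on day d to
sunrise on day d+1 — because the species' single activity phase is
nocturnal; a midnight-anchored day would split it.  The hour containing
sunrise belongs partially to two biological days and yields two partial
rows; the coverage rule below removes them from daily means.

Missing-data policy (our own; the analysis needs one even though clean
data make it invisible): an hour enters daily means only with >= 80%
sample coverage, and a day enters modelling only with >= 20 complete
hours.  Both thresholds are configurable.

## Solar events

Sunrise and sunset come from the NOAA low-accuracy solar-position
equations (declination and equation of time from the Julian-century
polynomials, hour angle at solar elevation -0.833 degrees — standard
refraction plus half-disc), with one refinement pass that re-evaluates the
ephemeris at the first-pass event time.  Mid-latitude summer events agree
with a minute-grid elevation scan to well under two minutes.  Polar
day/night raises an explicit `NoSunEventError`; nothing is silently
substituted.  One site coordinate and a fixed UTC offset serve the whole
study area (a few kilometres across, June-August contains no DST
transition in practice; the offset is a config value).

## Weather and heatwaves

Precipitation is a strict binary presence factor (> 0 mm, no trace
threshold) at the hour, day, or heatwave-period scale.  Weather days
follow the same sunrise-anchored biological days as activity so response
and covariates share one clock; a calendar-day mode exists for comparison
with providers that report midnight-to-midnight days.

A day *qualifies* as hot when its biological-day mean temperature strictly
exceeds 24 degrees C — the upper edge of the species' summer thermoneutral
zone — and at least 23 of its hours carry data.  A heatwave is a maximal
run of consecutive qualifying days (single-day events included, lengths in
whole days; calendar gaps split runs).  The "23+ h" condition is read as a
per-day coverage requirement rather than a rolling 23-hour window, because
heatwave durations are integer day counts; a rolling-window variant is
deliberately out of scope.

## Movement metrics

After filtering fixes to DOP in [1, 7] (inclusive), three per-day metrics
are computed with the haversine formula on a sphere of R = 6371.0 km
(ellipsoidal corrections are far below GPS error at this spatial scale):
daily distance (sum of step lengths), maximum net squared displacement
anchored at the day's first fix, and mean step speed.  Steps longer than a
gap cap (default 4x the nominal 30 min fix interval) are excluded from
distance and speed — a silent interval says nothing about the path — but
not from NSD, which needs only the positions.  The per-day NSD anchor and
the gap cap are this package's choices; both are exposed.

## Statistical models

All three models are Gaussian with identity link and an animal-level
random intercept for repeated measures.

**Hourly model.**  Response: hourly sum of smoothed VeDBA.  Terms: a
thin-plate-style smooth of hourly temperature, a cyclic cubic smooth of
clock hour (periodic at 24 h), their tensor-product interaction
(interaction-only construction), each split by the hour's precipitation
presence, plus a linear precipitation main effect.

**Seasonal model.**  Response: daily mean VeDBA (or, post hoc, a daily
movement metric).  Same structure with daily maximum temperature and day
of year (non-cyclic — a single summer has no wrap-around), split by the
day's precipitation presence.

**Engine.**  The smooth models are penalized regression splines built in
this package: cubic B-spline bases on equally spaced knots with
second-order difference penalties (P-splines), a wrap-around basis and
penalty for the cyclic hour term, and tensor-product interactions as
row-wise Kronecker products of sum-to-zero-constrained marginals (the
constraint removes main-effect leakage, so `ti` is pure interaction).
Group dummies with a ridge penalty, constrained to sum to zero so the
grand mean stays in the fixed intercept, implement the random intercept.
Smoothing parameters — one per penalty, including the random-intercept
ridge — minimize GCV, located by two coordinate-descent passes over a
log-spaced grid followed by a Nelder-Mead polish.  GCV is an
REML-equivalent criterion for Gaussian smoothing; the parameter-recovery
tests, not the selector, define correctness.  Basis sizes default to k=12
for the cyclic hour smooth (the diel profile holds a night plateau plus
narrow crepuscular peaks on 24 support points; k=10 measurably biases the
night/day contrast), k=10 for the seasonal smooths and 5x5 for tensor
interactions; all are arguments.  Term significance is an approximate Wald
test on the Bayesian coefficient covariance, rank-truncated to the term's
effective degrees of freedom — a screening statistic, conservative under
heavy penalization (type-I error measured below nominal in the null
calibration test).

**Heatwave model.**  One row per animal x heatwave period: the animal's
mean daily VeDBA over the period against z-scored period-mean daily
maximum temperature, z-scored length in days, precipitation presence and
both covariate x precipitation interactions; maximum likelihood via
statsmodels MixedLM.  Confidence intervals use a t reference with
cluster-level degrees of freedom (number of heatwaves minus number of
fixed effects): the weather covariates vary only between heatwaves, so the
default large-sample z intervals are anti-conservative (measured ~93%
coverage at nominal 95% over 1000 null replicates; the t correction
restores ~94-95%).  Goodness of fit is reported as Nakagawa marginal and
conditional R² (fixed-effect variance over, respectively plus, the random
and residual variances).  The model refuses rank-deficient designs (a
single heatwave, or fewer than two heatwaves in a precipitation level)
instead of returning unstable estimates.

**Effect contrasts.**  Population-level prediction sets the random effect
to zero.  `percent_change` averages predictions over two clock-hour
windows at a fixed temperature and precipitation level and returns the
percent change; `night_day_elevation` contrasts 22:00-04:00 (wrapping
midnight, hour grid {22,23,0,1,2,3}) against 05:00-21:00, averaging
predictions over an 11-point quantile grid of the observed temperatures
and over both precipitation levels weighted by their observed frequencies,
as the ratio of weighted window means.  Because contrasts are ratios, the
zero-random-effect convention is part of their definition.

## The synthetic campaign

The generator's defaults are the study conditions every recovery test
runs under:

* **Temperature**: seasonal mean 19.6 C with a 2 C modulation peaking near
  DOY 200, a 5 C diel sinusoid peaking at 15:00, and day-level AR(1)
  anomalies (phi 0.75, stationary sd 4 C) chosen so simulated summers span
  roughly 8-37 C hourly — the range a central-European summer record
  shows.  Optional additive day-level boosts inject heatwaves with known
  start and length.
* **Precipitation**: dry-day probability 0.42; within wet days each hour
  is wet with probability 0.25 and depths are Gamma(0.6, 2.0) mm.  Note
  that aggregation to sunrise-anchored days mixes adjacent calendar days,
  so the realized fraction of fully dry *biological* days is lower
  (~20-25%) than the calendar-day parameter.
* **Activity** (hourly VeDBA-sum scale, arbitrary units): baseline 1000 x
  a diel profile x exp(slope x (T - 20)) x exp(-0.002 x (DOY - 182)) x
  exp(animal intercept, sd 0.15) x exp(noise, sd 0.15).  The temperature
  slope is -0.03/C on dry hours and 0 on wet hours — the rain-dependent
  heat response the hourly model must recover.  The *nocturnal multiplier*
  (default 1.6) is defined operationally as the ratio of mean intensity
  over 22:00-04:00 to 05:00-21:00; the night-weight curve and the dawn
  (04:00) and dusk (21:30) acrophase bumps are balanced within those two
  windows so the parameter equals that contrast exactly, whatever the bump
  amplitudes.  This makes "recover the 60% elevation" a well-posed target.
* **10 Hz streams**: a slowly rotating gravity unit vector (~0.1 deg/s)
  plus 1-3 Hz sinusoidal bursts under 5 s Hann envelopes covering ~30% of
  each hour, with per-hour energy calibrated to the hourly intensity.
  Full-rate generation is only used for spans up to about a week; a whole
  season would be ~80 M samples per animal, far beyond what the tests
  need, so season-scale model tests consume the hourly generator directly.
  Noise-free intended intensities are always emitted as a sidecar table so
  recovery tests never re-derive truth from generator internals.
* **GPS**: biased correlated random walk around a home-range centre (step
  sd 150 m per 30 min fix, persistence 0.5, homing 0.05), with a
  configured fraction (default 0.15) of fixes drawn with DOP outside
  [1, 7].

What the generator does *not* emulate: behaviour-level structure (no
foraging/travelling regimes — bursts are statistically, not ethologically,
shaped), habitat or terrain, magnetometer channels, spatially varying
sunrise, tag failures other than simple gaps, and any dependence of
movement on weather.  Passing recovery tests therefore show that the
pipeline and models recover effects of the assumed multiplicative form
from data with realistic marginal structure — not that real field data
meet those assumptions.

## Problem sizes and numerical choices

The test suite runs the hourly-model recovery at 5 animals x 60 days x 24 h
(7,200 rows) over 50 replicate summers, the seasonal recovery at 5 animals
x 92 days over 50 replicates, and the mixed-model calibration at 30
heatwaves x 10 animals over 200 replicates — sizes at which one fit takes
a fraction of a second and the whole suite stays desk-scale.  Determinism:
every stochastic component draws from `numpy` Generators seeded per
component; identical configuration and seed reproduce outputs
byte-for-byte.  Degenerate inputs are handled explicitly: empty streams
return empty results, a single precipitation level collapses by-factor
smooths with a warning, constant responses yield flat fits, and
out-of-range covariates at prediction time are clamped to the training
hull rather than extrapolated with an unconstrained spline.

## Known limitations

* GCV can undersmooth relative to REML in small samples; smooth-term
  p-values are approximate and intentionally conservative.
* Fixed-temperature hour contrasts probe (hour, temperature) combinations
  that are thinly supported when temperature and hour are strongly
  confounded; the night/day elevation therefore averages over the observed
  temperature distribution instead of extrapolating.
* The heatwave model is estimable only when both precipitation levels
  contain at least two heatwaves; a single summer often fails this, as the
  pipeline's manifest records.
* The additive Gaussian models approximate a multiplicative, log-normal
  generating process; at the simulated noise levels the induced bias in
  the reported contrasts is within a few percentage points (quantified by
  the recovery tests), but it is not zero.
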