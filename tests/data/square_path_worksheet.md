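# Hand-computed haversine worksheet for the square-path fixture

Five GPS fixes (`square_path.csv`) trace a ~1.1 km x 0.7 km "square"
(equal 0.01-degree steps; the east-west legs are shorter because a degree
of longitude shrinks with latitude) at 30-minute intervals, returning to
the start.  All expected values below were computed independently of the
package with the haversine formula on a sphere of radius R = 6 371 000 m:

    d = 2 R asin( sqrt( sin^2(dphi/2) + cos(phi1) cos(phi2) sin^2(dlambda/2) ) )

## Step lengths (m)

| step | from -> to              | distance (m)  |
|------|-------------------------|---------------|
| 1    | (50.00,14.80)->(50.01,14.80) | 1111.949266 |
| 2    | (50.01,14.80)->(50.01,14.81) |  714.598532 |
| 3    | (50.01,14.81)->(50.00,14.81) | 1111.949266 |
| 4    | (50.00,14.81)->(50.00,14.80) |  714.747211 |

A pure 0.01-degree latitude step is R * 0.01 * pi/180 = 1111.949266 m,
matching steps 1 and 3 exactly.

## Daily metrics (one biological day, first fix = day anchor)

- daily distance  = sum of steps = **3653.244275 m**
- max NSD         = squared distance from fix 1 to the far corner
  (50.01, 14.81): 1321.812196^2 = **1747188.481188 m^2**
- mean speed      = mean(step / 1800 s) = **0.507395038 m/s**
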