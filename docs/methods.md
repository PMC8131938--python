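# Methods

`proteanflight` turns raw homing-flight logger files — 1 Hz GPS fixes, 4 Hz
barometric pressure, 10-second anemometer records at the release site — into
wind-relative airspeeds, terrain-annotated tracks, flight-mechanics
reference speeds, fine-scale variability statistics and mixed-effects
models of airspeed selection. This note describes the models and the
numerical choices, what the synthetic campaign generator does and does not
emulate, and the known limitations.

## Airspeed decomposition

Ground speed `Vg` and heading are taken between consecutive GPS fixes as
geodesic distance and initial azimuth on the WGS84 ellipsoid (vectorized
Vincenty inverse; checked against an independent geodesic library to
sub-millimetre agreement). The horizontal airspeed removes the measured
wind vector by the law of cosines,

    Vx = sqrt(Vg^2 + Vw^2 + 2 Vg Vw cos(theta)),

where `theta` in [0, 180] degrees is the unsigned circular difference
between the track heading and the meteorological ("from") wind direction.
The convention is fixed by requiring the formula to reduce to `Vg - Vw`
under a pure tailwind: `theta = 0` is a headwind, `theta = 180` a tailwind.
Total airspeed is the vector sum with the climb rate, `Va = sqrt(Vx^2 +
Vz^2)`, so `Va >= |Vz|` by construction.

Wind is a single per-flight mean vector (arithmetic mean speed, circular
mean direction) from the release-site anemometer, matching the study design
in which wind is measured only at the release site and flights with mean
wind above 2 m/s are discarded outright. Heading, being a direction, is
smoothed circularly (via unit-vector components).

## Barometric altimetry

Pressure is converted to altitude with the hypsometric equation anchored at
a calibration point measured in the 10 s before take-off:

    h = h_ref + (T_ref / L) * (1 - (p / p_ref)^(R L / (g M)))

with ISA constants (L = 0.0065 K/m, R = 8.31446 J/(mol K), g = 9.80665
m/s^2, M = 0.0289644 kg/mol) and `T_ref` defaulting to 288.15 K. Anchoring
at the daily reference removes day-to-day synoptic pressure changes; the
altitude *differences* that drive climb rate are insensitive to the exact
temperature (a 10 K error changes a 100 m climb by ~3 m). The 4 Hz
pressure stream is first averaged into the 1 Hz GPS frame (mean of the
samples in [t - 0.5, t + 0.5) per fix; fixes outside sensor coverage are
flagged missing, never invented), smoothed, then converted.

## Smoothing and differencing

Altitude and ground speed are smoothed with a centred moving average over
5 s (truncated, not padded, at the series ends, so constants are preserved
and the output length equals the input length). Climb rate, and forward
acceleration from `Va`, are forward first differences assigned to the
earlier sample, with the final sample carrying the last defined value.
Altitude is smoothed *before* differencing, and `Va` is assembled from the
smoothed components.

### A differential-smoothing artifact worth knowing about

The two derivation branches do not apply *exactly* the same effective
filter. Window-averaging the 4 Hz pressure into the 1 Hz frame and then
differencing gives the measured `Vz` a short asymmetric kernel
(~0.19/0.75/0.06 over three samples), while the GPS-derived speed carries a
single-sample kernel. The regressor in an airspeed-versus-climb-rate fit is
therefore slightly more low-passed than the climb-rate content of the
response, which *steepens* the fitted slope by roughly 3–4% at the default
fine-scale variability amplitudes (verified against the generator's ground
truth). Any pipeline built from these standard ingredients — window-mean
resampling, consecutive-fix speeds, consecutive-sample differences — shares
the artifact; it is documented rather than patched because each ingredient
is the field-standard definition.

## Exclusion rules

Four rules isolate the travelling section of each homing flight:

- **Wind filter** (flight level): mean wind > 2 m/s excludes the flight.
- **Circling**: a point is flagged when any 30 s window containing it
  accumulates at least 270 degrees of unwrapped heading rotation (both
  parameters configurable; the literature states no canonical rule, so the
  defaults are declared, testable choices).
- **Take-off / landing trims**: points within 200 m of the release before
  first leaving that radius, and within 200 m of the loft after last
  entering it.
- **Resting**: runs of ground speed below 3 m/s lasting at least 5 s —
  thresholds far below any plausible cruising speed, so travelling flight
  is never clipped.

The three point-wise masks are computed independently, so the surviving
point set does not depend on application order. The pipeline additionally
drops unflagged points within 5 s (one smoothing window) of any flagged
point: a smoothed value straddling an exclusion boundary carries excluded
behaviour (e.g. low-airspeed circling) into the travel segment, which
measurably biases downstream regressions. This guard band is off at the
module level (guard_s = 0) and on in the pipeline configuration.

## Terrain annotation

Elevation comes from an ESRI ASCII grid sampled bilinearly between
cell-centre values; land cover from a second grid sampled by nearest cell
(categorical), with integer codes mapped to {open, woodland} by a
config-supplied table. Altitude above ground is smoothed ASL minus the
sampled elevation; negative values are possible (barometric drift) and kept,
flagged, rather than clipped.

Routes are classified against a 465 m contour: **hill** when the bird flies
above the contour over ground at or above it for at least 10% of travel
time, **valley** when the ground stays below the contour throughout,
**mixed** otherwise. The fraction rule makes the classification invariant
to track densification.

**Climb-onset distance** is the along-track distance between the start of
the ascent into a hill and the point where ground elevation first reaches
the contour. "Start of the ascent" needs an operational definition: here it
is the beginning of the last sustained climb run — trend climb rate
(20-s-smoothed) at or above 0.3 m/s held for at least 10 s, with runs
separated by gaps of up to 10 s merged — that reaches the hill base. The
20 s trend window exists precisely because fine-scale (protean) altitude
variability would otherwise false-trigger the detector kilometres early;
its cost is a resolution of roughly ±0.2 km on the onset point.

**Plain altitude contrast** compares mean ASL of hill-bound versus
valley-bound flights over a configurable along-track window (default
500–1700 m from the release) that lies before any programmed climb.

## Flight power curve

Mechanical power is the classical three-component model: induced power
`k (m g)^2 / (2 rho V S_d)` over the wing disc `S_d = pi b^2 / 4` with
induced-power factor k = 1.2; parasite power `0.5 rho V^3 S_b C_Db` with
body frontal area `S_b = 0.00813 m^0.666` and body drag coefficient 0.2;
and a constant profile power equal to (8.4 / aspect ratio) times the
minimum of the two variable terms. `Vmp` minimizes `P(V)`; `Vmr` minimizes
`P(V)/V` (the tangent from the origin), each located by bounded
minimization on (0.05, 200) m/s to 1e-4 m/s. `Vmp < Vmr` holds for every
valid morphology because `P(V)/V` is minimized where the chord from the
origin touches the convex curve, always to the right of the minimum. For a
pigeon-like bird (0.455 kg, 0.66 m span, 0.035 m^2 wing area) the defaults
give Vmp ≈ 11.3 m/s and Vmr ≈ 17.0 m/s. This is a deliberately
self-contained, documented model — exact numerical agreement with more
detailed aerodynamic packages is not claimed; all constants are
configurable. Air density is fixed at sea-level ISA by default (flights
span a few hundred metres ASL where the correction is ~4%).

## Variability metrics

Per travel segment: mean, s.d., within-flight range (max − min) and maximum
of `Va`; median and IQR of climb rate for the climbing (`Vz > 0`) and
descending (`Vz < 0`) subsets; median, IQR and range of acceleration;
maximum climb angle and the fraction of strictly positive climb angles at
or below 5 degrees; tortuosity (along-track geodesic length over the
release-to-loft geodesic); and the **extra vertical distance**: the sum of
|altitude changes| of the 5-s profile minus the same sum for the
20-s-smoothed profile, both taken over the full-window interior so that
end-of-series window truncation cannot register as vertical distance. The
metric is offset-invariant, non-negative, exactly zero on ramps and
constants, and counts both climb and descent (a distance, not a
displacement); a climb-only variant is a documented alternative reading.
All quantiles use linear interpolation (Hyndman–Fan type 7).

## Mixed-effects models

All models are linear mixed models with crossed random intercepts for day
and bird, fitted by REML (statsmodels MixedLM with a constant group and one
variance component per factor; optimizer cascade lbfgs → powell → default,
keeping the best converged likelihood). Likelihood-ratio comparisons refit
both models by ML. Per fixed term the tables report the raw estimate, the
estimate with continuous predictors centred and scaled (dummies untouched,
so categorical effects agree between columns), s.e., t, a 1-df Wald
chi-square and its p-value. Marginal R² is the fixed-effects variance share
of (fixed + random-component + residual) variance; conditional R² adds the
random components (Nakagawa-style decomposition), so conditional ≥ marginal
on every fit.

**Sampling rate and honest inference.** At 1 Hz with 5-s smoothing,
neighbouring observations are strongly dependent: a full-rate fit
understates the slope standard error by nearly a factor of two, and its
chi-squares are correspondingly inflated. The Table-1-style pipeline report
fits at full rate for comparability with the field convention and carries
this caveat; every parameter-recovery analysis in this package instead
thins to one observation per 15 s (≈1.5 times the residual correlation
time), which restores near-nominal confidence-interval coverage (measured
91–92/100 for the programmed airspeed–climb slope across replicate
campaigns).

**Phase-specific fits.** Splitting on the sign of the *measured* climb rate
is selection on an error-laden variable: near zero the subsets exchange
misclassified points, which flattens one side's slope and steepens the
other's even when the generating slope is identical in both phases (at
default conditions roughly −1.12 climbing vs −1.47 descending against a
programmed −1.24). Asymmetry in such fits should not be read as behavioural
asymmetry without a measurement-error model.

## The synthetic campaign generator

The generator emulates the *statistical structure* the analysis assumes,
not flight dynamics. A campaign is 7 birds × 4 days (one flight per bird
per day), 360 s of travel at 1 Hz per flight, in a simulated valley running
7 km north from a release site to a loft, flanked east by a Gaussian ridge
(valley floor 430 m, peak 590 m, so the 465 m contour is crossed only on
the ridge). Route class and wind speed follow a deterministic schedule over
the bird × day grid — 7 hill flights, 7 flights with wind above the 2 m/s
filter — so the campaign composition is identical for every seed, while
every noise process is seed-driven (byte-identical outputs per seed).

Per flight: a 45 s circling bout at the release (12 deg/s, ~40 m radius,
designed to trip the circling detector and the take-off trim); then travel
along the route centerline (gently sinuous for valley flights, bowing east
over the ridge for hill flights). True airspeed follows

    Va(t) = (20 + bird + day) - 1.24 * Vz(t) + epsilon(t) + landcover term,

with bird and day intercepts (s.d. 1 m/s each), a mean-reverting
(discrete Ornstein–Uhlenbeck) speed perturbation (s.d. 2 m/s, correlation
time 10 s) and a −0.165 m/s woodland effect. Climb rate is the route
altitude-profile gradient (kinks rounded over ~150 m — birds do not change
climb rate as a step function) times the nominal cruise speed, plus the
increments of an altitude OU perturbation (s.d. 3 m, correlation time 8 s);
using the nominal rather than realized speed in the gradient term keeps Vz
independent of the speed perturbation, so the programmed linear Va–Vz
relation holds exactly in the ground truth. Hill flights fly a programmed
50 m higher than valley flights over the pre-hill plain and begin their
sustained climb a programmed 2 km before the 465 m contour. Ground
velocity is air velocity plus the wind vector (solved so the track follows
the centerline); true altitude is converted to 4 Hz pressure through the
inverse hypsometric formula before sensor noise (0.05 hPa) is added, and
GPS positions get 1 m Gaussian noise. These amplitudes approximate the
reported fine-scale variability of real homing flights (within-flight speed
range ~10 m/s, climb-rate medians of a few tenths m/s); they are an
emulation, not a fit.

What the generator does **not** emulate — and therefore what passing tests
cannot show about real data: wingbeat-frequency signal and aerodynamic
manoeuvre dynamics; spatially structured wind (the generator's wind is
constant per flight, so the per-flight mean-wind design is exact by
construction, not merely adequate); GPS error autocorrelation and altitude-
dependent pressure-sensor behaviour; navigation, route learning and any
predator-response behaviour; and real Corine/DSM raster idiosyncrasies
(projection artifacts, NODATA holes).

## Problem sizes and determinism

Default analyses run a 28-flight campaign (~11 000 track points) in a few
seconds on one core. The replicate study behind the coverage statement uses
100 simulated campaigns. Identical configuration and seed give
byte-identical campaign files and report checksums; all randomness flows
from numpy `SeedSequence` spawns of the single campaign seed.

## Known limitations

- The 2 m/s wind filter plus a single anemometer means the wind correction
  is only as good as the release-site measurement; en-route wind variation
  becomes airspeed error. Per-point wind interpolation is config-exposed
  but defaults off.
- Barometric altitude is relative to the take-off calibration; slow
  synoptic drift over a flight appears as spurious altitude trend (real
  data; the generator drifts nothing).
- Full-rate (1 Hz) mixed-model statistics are anti-conservative, as
  discussed above; use the thinned fits for inference.
- The climb-onset detector's 20 s trend window trades ±0.2 km of onset
  resolution for robustness to protean variability.
- The power-curve model is a three-component abstraction; its absolute
  power values are indicative, though the characteristic-speed *ordering*
  and scalings are robust.
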