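# proteanflight

Fine-scale analysis of high-frequency bird flight tracks: from raw 1 Hz GPS,
4 Hz barometric pressure and release-site wind logs to wind-relative
airspeeds, terrain-annotated trajectories, flight-power reference speeds,
protean-variability statistics and mixed-effects models of airspeed
selection.

## The problem

Flapping flight follows a U-shaped power curve P(V): hovering and fast
flight are expensive, and two reference speeds fall out of the curve — the
minimum power speed V<sub>mp</sub> (argmin P) and the maximum range speed
V<sub>mr</sub> (argmin P/V). How a bird places its airspeed relative to
these speeds, and how it modulates speed against climb rate, terrain and
land cover, reveals what currency (time, energy, risk) drives the flight.
Homing pigeons carrying high-frequency loggers also show marked
second-by-second variability in speed and altitude — apparently
inefficient "protean" movement that may serve predator evasion. Measuring
any of this requires a careful chain: barometric altimetry calibrated at
take-off, wind-corrected airspeed from GPS ground speed,

&nbsp;&nbsp;&nbsp;&nbsp;V<sub>x</sub> = √(V<sub>g</sub>² + V<sub>w</sub>² + 2·V<sub>g</sub>·V<sub>w</sub>·cos θ), &nbsp;&nbsp; V<sub>a</sub> = √(V<sub>x</sub>² + V<sub>z</sub>²),

exclusion of circling, rest and take-off/landing phases, and mixed models
(crossed random intercepts for bird and day) such as
V<sub>a</sub> ~ V<sub>z</sub> + land cover + altitude + V<sub>z</sub>:altitude.

`proteanflight` implements this chain end to end for movement ecologists
working with biologging data, together with a synthetic campaign generator
that emulates the statistical structure of a homing study (valley/hill
routes over a ridge, programmed airspeed–climb slope, anticipatory climbs,
bird/day random effects, mean-reverting fine-scale variability), so every
stage is testable with known ground truth and without any field data.

## Worked example

```python
import numpy as np
from proteanflight import SimConfig, simulate_campaign, RunConfig
from proteanflight.pipeline import campaign_observations
from proteanflight import stats_models as sm, variability as var
from proteanflight import flight_power as fp, terrain as ter

campaign = simulate_campaign(SimConfig(seed=1))   # 7 birds x 4 days
cfg = RunConfig()
travel, routes, obs = campaign_observations(campaign, cfg)

reports = {fid: var.flight_report(f.points) for fid, f in travel.items()}
res = sm.fit_lme(obs, "va ~ vz", thin=cfg.recovery_thin)
contrast, _ = ter.plain_altitude_contrast(
    {fid: f.points for fid, f in travel.items()}, routes,
    cfg.terrain.plain_window_m)
```

which prints, for seed 1:

```
flights included: 21 of 28
mean airspeed: 20.2 m/s
within-flight speed range: 10.6 m/s
airspeed-climb slope: -1.23 (95% CI -1.47 to -0.98)
hill-vs-valley plain contrast: 51.1 m
mean climb onset: 2.08 km before the hill
bird01: mass 0.492 kg, Vmp 11.4 m/s, Vmr 16.8 m/s
```

Reading the numbers: 7 of 28 flights are dropped by the 2 m/s wind filter.
Birds cruise near 20 m/s — well above this morphology's V<sub>mr</sub> —
yet speed swings by ~10 m/s within a flight (the protean signature). The
mixed model recovers the airspeed–climb trade-off programmed into the
generator (−1.24 m/s per m/s of climb; the CI covers it), hill-bound birds
fly ~50 m higher over the plain than valley-bound birds, and they begin
climbing ~2 km before the hill, as programmed.

The same pipeline runs from the shell on any campaign directory, synthetic
or real:

```bash
proteanflight simulate --seed 1 --out campaign/
proteanflight derive --raw campaign/ --out analysis/
proteanflight report --out analysis/
```

`analysis/report/` then holds the exclusion ledger, per-flight and pooled
variability tables, per-bird power-curve speeds and the mixed-model tables;
`analysis/derived/` holds one annotated CSV per flight.

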