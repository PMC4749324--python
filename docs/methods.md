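# Methods

## The exposure model

`expotra` estimates the task-level airborne concentration (ppm) a worker
inhales while handling a volatile substance, in the banded screening style
of the ECETOC-TRA worker model:

```
modelled = E0(vp) · A(duration) · B(fraction) · C(LEV) · D(mask)
```

* **E0**, the *initial exposure*, is the unmitigated concentration assigned
  from the substance's vapor pressure `vp` (mbar at room temperature). It
  is represented as a piecewise **log-linear curve**: exposure is linear in
  `ln(vp)` between configurable `(vp, ppm)` anchors and clamped to the end
  ordinates outside them. The shipped anchors — (0.2 mbar, 10 ppm),
  (20, 50), (300, 100) — sit at round values near the geometric midpoints
  of the TRA low (<5 mbar), medium (5–100) and high (>100) volatility
  bands. They are placeholders for a site calibration: the reference
  calibration is published only as a figure, so the curve's *shape family*
  and configurability, not fixed constants, are the contract here.
* **A–D** are multiplicative reduction coefficients in (0, 1], looked up in
  banded tables. Default duration bands: ≤15 min → 0.1, ≤60 → 0.2,
  ≤240 → 0.6, above → 1. Default fraction bands: ≤1 % → 0.1, ≤5 % → 0.2,
  ≤25 % → 0.6, above → 1. LEV present → 0.1, filtering mask worn → 0.001.
  Bands are half-open below and **closed above**: a 15-minute task takes
  the ≤15 band's smaller coefficient. A value above every configured band
  yields coefficient 1 and a logged warning.

Three constants are fixed by the model's published calibration and are hard
defaults: ethanol (CAS 64-17-5) bypasses the curve with `E0 = 200 ppm` and
may carry its own duration-coefficient table (the shipped ethanol table
equals the standard one, flagged as a placeholder); benzene (CAS 71-43-2),
handled only under laboratory hoods, uses `C = 0.03` when LEV is present;
the mask coefficient is `D = 0.001`.

A second, independently configured parameter set tagged `ecetoc_tra_v3`
represents the unmodified TRA v3 worker model for side-by-side comparison:
same curve/band placeholders, **no** substance overrides, and the generic
TRA mask factor 0.1.

Assumptions and limits: inhalation route only (no dermal/oral, no
aerosols); vapor pressure at a single room-temperature reference (the model
is validated over 18–25 °C, so no temperature correction); exposures are
per-task concentrations, not 8-h TWAs — no averaging-time conversion is
applied because the reference method states none. mg/m³ ↔ ppm conversion
uses the ideal-gas molar volume at the given temperature (default 25 °C)
and 1013.25 mbar.

## Sampling QC

A measurement is one personal air sample drawn through three sorbent tubes
in series. It is valid for model validation iff all rules pass:

* **breakthrough** — second-tube mass strictly above 5 % of the total mass
  over all three tubes invalidates (exactly 5 % passes; a zero total passes
  with 0 %). The denominator is the *total* recovered mass, reading the
  governing standard's "total recovered quantity" as the three-tube sum.
  The third tube is a sentinel: mass on it logs a warning but does not by
  itself invalidate, since the rule names only the second tube.
* **humidity_range** — relative humidity within 10–80 % (inclusive).
* **temperature_range** — 18–25 °C (inclusive), the method's validated window.
* **shelf_life** — analysis at most 16 days after sampling.

Failing samples are flagged and excluded from validation but never dropped
from the record.

## Validation statistic

The model's design goal is *never to underestimate* exposure, so the
acceptance statistic is one-sided: the percentage of
(estimate, QC-valid measurement) pairs with `modelled ≥ measured`, overall
and per substance / per operation class. Ties count in the model's favour;
a strict `>` count is reported alongside for the stricter reading.
Below-detection-limit measurements are compared at their reported value (no
LOD/2 substitution by default). Joining is by `scenario_id`; several
measurements may validate one scenario, and every unmatched or QC-excluded
record is listed in a pairing report.

## Record cards

Annual personal exposure record cards list, per operator-year, every
operation on a substance that passes the inhalation-hazard phrase gate:
chemical and CAS, operation type, number of operations, unit duration,
substance fraction, protection measures and the per-operation modelled
exposure. Scenarios aggregate on (substance, operation, duration band,
fraction band, protection flags) so repeated similar tasks collapse into
counted entries; raw duration extremes are kept per entry for audit, and
the entry's fraction and exposure are the group maxima (conservative).
Cumulative annual doses are deliberately not computed. The default hazard
gate covers inhalation-route R-phrases (R20, R23, R26, …, R68) and CLP
statements (H304, H330–H336, H340, H350/H350i, H351, H370–H373); it is a
documented placeholder to be replaced by the deploying site's regulatory
list. Combination phrases (e.g. R23/25) match on any component.

## Synthetic campaigns

`generate_campaign` emulates the structure of a factory monitoring
campaign: by default 430 samples over 27 substances (ethanol and benzene
plus synthetic-CAS substances with log-uniform vapor pressures over
0.05–500 mbar), operation classes drawn with the reference shares
54.5 / 32.5 / 11.6 % renormalised to sum to 1, durations lognormal with
median 20 min and GSD 3 (clipped to 1–480 min, reflecting the industry's
many short handling tasks), half of all handling at 100 % purity, LEV in
40 % and masks in 25 % of scenarios. Measured concentrations are the
generating model's prediction times a lognormal factor with geometric mean
`mu_g` (default 1: median-unbiased) and geometric SD `sigma_g` (default
2.5, a typical occupational-hygiene dispersion); `model_distortion` scales
the generating model so over/under-estimating regimes can be constructed.
Per-rule QC failures are injected independently at 5 % (breakthrough) and
2 % (each other rule). Everything is drawn from one
`numpy.random.default_rng(seed)`, so a spec reproduces byte-identical
campaigns.

What the generator does *not* emulate: correlation between substances and
operations, within-day time series, operator-specific habits, co-exposure
to mixtures, or the reference dataset's actual values. Green tests on
synthetic campaigns therefore demonstrate the pipeline's statistical and
algebraic correctness (e.g. the overestimation fraction converges to 50 %
under median-unbiased noise), not field calibration of the curve or bands.

A separate six-scenario `known_answer_campaign` has all expectations
derived by hand (vapor pressures placed on or between curve anchors, one
deliberate breakthrough failure, one non-hazardous substance) and anchors
the end-to-end golden tests: modelled exposures, QC verdicts, a 75 %
overestimation fraction over its four valid pairs, and record-card counts.

## Numerical choices

* Factorization is exact float multiplication; tests check it to 1e-12
  relative.
* Curve interpolation is linear in `ln(vp)`; anchors must strictly increase
  in vp with non-decreasing ordinates, validated at construction.
* Band ties take the band whose upper bound equals the value (the smaller
  coefficient — conservative for the operator-protection reading).
* Unit round-trips (ppm↔mg/m³) are exact to 1e-9 relative by construction.
* Problem sizes: property suites use the 430-sample default campaign;
  convergence checks use one 10,000-sample campaign (≈0.6 s end to end),
  with binomial 3-sd tolerances computed from the realised pair count.

## Known limitations

The shipped curve anchors, band coefficients and hazard-phrase list are
documented placeholders; reproducing the reference field calibration
(98 % overestimation vs 37 % for classic TRA) requires transcribing the
calibrated curve/band figures and the measured dataset, which this package
cannot ship. Coefficient C models local exhaust ventilation only, not
general room ventilation. Vapor pressures are single-point; process
temperatures outside 18–25 °C are out of scope.
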