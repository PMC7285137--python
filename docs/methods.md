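# Methods

This note documents the statistical procedures implemented in `pedree`, the
assumptions behind the synthetic-data generators, and the numerical
conventions that pin down otherwise ambiguous details.

## Study design being modelled

The package reproduces, as reusable code, the external cross-validation of
REE prediction equations in a pediatric cohort stratified four ways: girls
without obesity, girls with obesity, boys without obesity, boys with
obesity ("without obesity" pools underweight, normal weight and
overweight). Eligibility keeps subjects with age ≤ 18 years (inclusive) and
respiratory quotient inside [0.67, 1.3] (exclusion is strict: RQ < 0.67 or
RQ > 1.3; a missing RQ excludes with its own reason code). One row is one
subject; repeated measures are out of scope.

## Indirect calorimetry

A measurement session is a minute-indexed series of VO₂, VCO₂ (L/min) and
minute ventilation VE (L/min). Processing:

1. **Acclimation.** The first 10 min are discarded outright.
2. **Steady state.** The earliest sliding window of 5 consecutive minutes
   in which the coefficient of variation (100·sd/mean, sample sd) of
   per-minute RQ is < 5% and of VO₂ and VE each < 10%. "Variation" is
   implemented as the CV — the convention of calorimetry software — and the
   comparisons are strict, so a window sitting exactly on a threshold does
   not qualify. The detector is tested against exhaustive window
   enumeration.
3. **Averaging.** VO₂ and VCO₂ are averaged from the first minute of the
   steady-state window to the end of the recording, requiring ≥ 20 min;
   shorter recordings fail QC (`short_recording`), as does the absence of
   any qualifying window (`no_steady_state`).
4. **Weir conversion.** mREE = (3.941·V̄O₂ + 1.106·V̄CO₂) kcal/min × 1440.
   The abbreviated (protein-free) Weir coefficients are forced by the fact
   that only O₂ and CO₂ are recorded — no urinary nitrogen is available.
   RQ = V̄CO₂/V̄O₂ from the same means.

Open choices resolved here: the averaging period *begins at* (not merely
after) the steady-state window, and eligibility RQ is the whole-period RQ —
both the literal reading of the measurement protocol.

## Anthropometry

BMI = weight (kg) / height (m)². Standard-deviation scores use the Cole LMS
transform, `z = ((x/M)^L − 1)/(L·S)`, switching to the limit `ln(x/M)/S`
for |L| ≤ 1e−7. L, M and S are linearly interpolated in age within the
reference grid; extrapolation outside the grid is an error, never a guess.
Weight status from BMI SDS: underweight < −1.644 ≤ normal < 1.036 ≤
overweight < 1.644 ≤ obesity (each boundary belongs to the class on its
right).

The national (Italian) growth-reference tables are licensed data and are
not redistributed. `synthetic_growth_reference()` supplies a smooth
synthetic stand-in over ages 2–20 (BMI: L = −1.5, S = 0.13, median rising
~0.38 kg/m² per year; height: L = 1, S = 0.04 with a pubertal plateau;
weight derived from both) so that every stage of the pipeline runs and is
testable self-contained. Any real LMS table in the documented CSV schema
can be dropped in; the fixture must not be used for clinical
classification.

## Equation registry

The ten equations are stored as data (one CSV row per sex × age-bracket
coefficient set) with a checksum test pinning the file. Design choices:

* brackets are half-open [lo, hi) years; the lowest starts at 0 and the
  topmost extends to ∞, so every equation scores every subject — the
  validation deliberately applies equations outside their development age
  ranges;
* weight-only equations carry a zero height coefficient so the evaluator
  has a single linear form;
* native units are preserved in the data file (Schofield and WHO in
  kcal/day, Henry/Molnár/Müller in MJ/day, heights in cm or m as published)
  and converted once at evaluation, MJ → kcal at 239.006 (4.184 kJ/kcal);
* the Müller equation is the age 5–17 anthropometric variant
  (0.02606·W + 0.04129·H + 0.311·male − 0.08369·age − 0.808 MJ/day), the
  children's form of that family, consistent with pediatric medians; the
  adult whole-sample variant is systematically ~200–300 kcal/day high in
  this population.

Each registry entry self-validates at construction (finite coefficients,
gap-free bracket tiling per sex).

## Accuracy statistics

For index-aligned pairs (mREE, eREE), all per equation × stratum and for
the pooled cohort:

* absolute bias eREE − mREE (kcal/day), percent bias 100·(eREE − mREE)/mREE,
  summarised as median and IQR (25th/75th percentiles, linear interpolation
  between closest ranks);
* MAPE = mean |percent bias| (identically, by construction);
* CCF = fraction with |percent bias| ≤ 10% (boundary inclusive, matching
  the "within 10%" clinical criterion), with exact Clopper–Pearson 95%
  intervals via Beta quantiles: low = B(α/2; k, n−k+1), high =
  B(1−α/2; k+1, n−k), degenerate ends 0 and 1. The implementation is tested
  against a brute-force inversion of the binomial tails for all n ≤ 30 and
  its exact coverage (computed by summing the binomial pmf) is verified to
  be ≥ 95% on a grid of p and n.
* Bland–Altman: point sets of absolute and percent difference against the
  pair average, plus an OLS fit of percent difference on average; the
  proportional-bias flag is a two-sided slope t-test at α = 0.05 (a formal
  test where visual inspection is the tradition, to make the flag
  reproducible). Limits of agreement are deliberately not computed: they
  are not interpretable in the presence of proportional bias.
* Paired median difference: the default inference is a seeded nonparametric
  bootstrap (2000 resamples) of the median difference with a
  normal-approximation p-value. Intercept-only median regression with
  Greene-sandwich robust standard errors is available
  (`method="quantreg"`), but in seeded null calibrations (multiplicative
  exchangeable noise, n = 80–500) its type-I error was 0.02–0.03 at nominal
  0.05 while the bootstrap sat at 0.050, so the calibrated route is the
  default. Degenerate all-zero differences return p = 1, flagged.

Display rounding (half-up; integer kcal, one-decimal percentages,
two-decimal CI bounds) happens only in the rendering routine — every stored
number is full precision.

## Synthetic cohort generator

The generator is the package's stand-in for the (undeposited) study data
and defines the conditions under which the pipeline is validated:

* stratum sizes default to 273/1194/116/843 (girls without/with obesity,
  boys without/with obesity; 2426 in all);
* per stratum, age ~ truncated normal on [5, 18] centred on the published
  stratum median with sd = IQR/1.349 (girls 15 (12;16) and 15 (13;16),
  boys 12 (10;15) and 15 (12;16));
* BMI SDS ~ truncated normal centred on the published stratum median
  (0.80, 2.80, 0.69, 2.84; sd again IQR/1.349), truncated at the 1.644
  obesity cutoff on the side the stratum requires, so stratum membership is
  exact by construction;
* height is drawn via a N(0,1) height-SDS (truncated at ±2.5) through the
  growth reference; weight = BMI × height², making BMI SDS, weight and
  height mutually consistent;
* mREE = eREE_gen(subject) × exp(ε), ε ~ N(0, σ²), with the Molnár surface
  as default generator and σ = 0.10. The lognormal error is the load-bearing
  choice: the within-10% event 0.9 ≤ e^ε ≤ 1.1 gives the closed form
  CCF = Φ(ln 1.1/σ) − Φ(ln 0.9/σ), ≈ 0.684 at σ = 0.10 — inside the 0.6–0.8
  band reported for the best equations — and makes parameter recovery
  exactly checkable;
* RQ ~ Uniform(0.75, 0.95).

A single seeded `numpy` generator is threaded through all sampling; no
global state. Truncation pulls the realised stratum medians slightly toward
the truncation-free side of each target (e.g. ages a few tenths of a year
below the centre), but they remain inside the target IQRs, which is the
property the tests assert.

What the generator does **not** emulate: the real data's skewness and
covariance beyond medians/IQRs, centre effects, measurement-device error
structure, or any systematic discrepancy between a child's true REE and
*every* equation surface. Consequently, passing tests demonstrate that the
pipeline recovers known structure, not that any equation is accurate in
real children; and the generating equation's advantage over rivals is only
identifiable where the CCF gap exceeds binomial noise — in the smallest
stratum (n = 116) the Molnár, Mifflin and Harris–Benedict surfaces are
nearly collinear for lean boys and the top rank legitimately flips between
seeds, which the tests treat as within-noise rather than failure.

The trace generator produces constant-level channels with Gaussian noise at
per-channel CVs, optional spike/drift artifacts, and floors non-positive
values at a small epsilon (logged).

## Pipeline and reproducibility

`run_validation` chains eligibility → anthropometry → prediction → report
and writes full-precision and display-rounded tables, per-group dot-chart
data (median percent bias; CCF with CI), Bland–Altman point sets, and a
manifest with the config snapshot, the coefficient-file checksum and a
sha256 per output. Fixed inputs give byte-identical outputs; manifests
contain no timestamps. The population summary counts age exactly 13 as an
adolescent (the "< 13 vs ≥ 13" split leaves the boundary to the older
class by convention, documented here).

## Problem sizes used in the test suite

The suite exercises full-size cohorts (2426 subjects) where stratum
structure matters, 10 seeded replicates for the closed-form CCF recovery,
200 random 60-min traces for the steady-state oracle, 400 seeded
replicates for the type-I calibration of the median-difference test, and
exhaustive (count, n ≤ 30) enumeration for the binomial interval oracle.

## Known limitations

* The synthetic growth reference is a fixture, not a published standard;
  SDS values are only internally consistent.
* The WHO, Schofield, Henry, IOM, Molnár, Müller, Mifflin and
  Harris–Benedict coefficients are transcribed from their original
  publications; equations published in multiple variants (notably Müller)
  are pinned to the variant documented above.
* The bootstrap median-difference p-value relies on a normal approximation
  of the bootstrap distribution; for heavily discrete data a percentile
  bootstrap would be preferable.
* No multiple-testing correction is applied across equations or strata, by
  design.
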