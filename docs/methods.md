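# Methods notes

This note records the models, the tunable parameters that matter, the
numerical choices, and what the synthetic-data experiments do and do not
demonstrate.

## The estimand

For each species-cell-year unit, the estimand is the pair of days-of-year
at which 10% and 50% of the season's adult activity has occurred — the
quantiles of the normalized within-season activity density ("flight
curve"). The two data streams estimate the same quantity by different
routes, which is what makes the cross-stream comparison meaningful.

## Survey stream: penalized Poisson spline

Counts at site *i*, day *d* follow `y ~ Poisson(mu)`,
`log mu = f(d) + s_i`, assuming within-cell synchrony of phenology with
site-varying abundance.

- **Basis/penalty:** cubic B-splines, 17 basis functions spread over the
  unit's observed season (first to last survey DOY), second-order
  difference penalty; the basis dimension shrinks automatically when a
  unit has fewer distinct survey days. Second-order differencing leaves
  linear trends unpenalized, so heavy smoothing degrades gracefully
  toward log-linear rather than flat.
- **Smoothing parameter:** GCV over a 9-point log-spaced grid
  (1e-2…1e4) using `n·deviance/(n−edf)²`; a `fixed_lambda` bypass exists
  and bootstrap refits reuse the full-data GCV choice (re-selecting
  lambda inside every resample roughly triples cost and mostly adds
  noise to the interval endpoints).
- **IRLS:** penalized normal equations, deviance tolerance 1e-8, max 100
  iterations, ridge 1e-8 on all coefficients for conditioning; linear
  predictor clipped at ±30 to avoid overflow at degenerate resamples.
- **Curve support:** the daily grid from the first to last survey date;
  density outside the sampled range is treated as zero. This truncation
  matters: if surveying starts after flight has begun, the 10% metric is
  right-shifted — the first-survey-absence eligibility rule exists
  precisely to exclude such units, and the censoring-direction test
  checks the residual effect's sign.
- **Site effects:** reference-coded dummies (the spline carries the
  level); sites with zero total count for a unit drop out of that unit's
  fit, since their effect diverges and they carry no shape information.
  Normalized-curve invariance to rescaling one site's counts is exact
  only in the interpolation limit; with a penalty it holds to ~1e-4,
  which the tests assert.
- **Degenerate units:** detections confined to a single DOY produce a
  point-mass curve at that day (both percentiles equal it) rather than a
  spline fit.
- **Percentiles:** smallest grid DOY whose cumulative (trapezoid) area
  reaches p/100, linearly interpolated between grid days; reported as a
  real, rounded only at presentation.
- **Bootstrap:** unique site-date visits resampled with replacement,
  B = 200 by default, percentile interval at level 0.95; a unit is
  flagged with no CI if more than half the resamples fail (e.g. no
  detections drawn).

## Incidental stream

Empirical quantiles (linear interpolation of order statistics — numpy's
default convention, chosen for continuity in n; configurable) of record
DOYs after exact dedup on (species, date, lon, lat) at full stored
precision, and a ≥10 records per unit eligibility rule. Bootstrap
B = 500 (each resample is one `np.quantile` call, so the larger B is
nearly free). Quantiles need no effort correction *if* effort is
constant over the season; the generator's effort model exists to create
the violation and measure its bias downstream.

A calibration caveat measured during development: the percentile
bootstrap for the 10% quantile is slightly anticonservative at small
samples — true coverage ≈ 0.85 at n = 30 records, recovering to ≈ 0.91–
0.93 at n ≈ 40–60 (the generator's default record density). The coverage
experiments therefore run at the generator's default rates; results at
10–20 records per unit should be read with wider-than-nominal intervals
in mind.

## Growing degree days

Single-sine daily degree-days between base 10 °C and upper 30 °C
(horizontal cutoff at the upper threshold), implemented in closed form
from the day's tmin/tmax and summed Jan 1–Jun 30 inclusive (181 or 182
days by calendar). The closed form agrees with 10,000-point numeric
integration to <1e-6 °C·day. Sub-cell temperature series are averaged to
cell-level tmin/tmax *before* the sine computation (documented order;
the alternative — GDD per pixel, then average — is a config switch away
at the caller level since `daily_gdd_single_sine` is vectorized).
A mean-only climate source can be used by reconstructing tmin/tmax from
an assumed diurnal range; the generator always supplies both.

## Mixed model

Random-intercept Gaussian LMM per stream and percentile, fit with
statsmodels' MixedLM on the paired units only (both streams estimable).

- No global intercept: the overwinter-class factor enters as five
  stage-level intercepts, so coefficients read directly as expected DOY
  at log(GDD) = 0 and the migrant/adult/pupa/larva contrasts of the
  standard dummy layout are recoverable by subtraction.
- log = natural log of cell-year GDD.
- AIC is always computed from the ML likelihood with
  k = fixed + variance parameters; selection runs on ML fits, the
  winner is refit by REML for reported coefficients. Ties break toward
  fewer parameters. Candidates fit on differing row sets raise.
- Observation-trait random effects (detectability, confusability) enter
  the candidate set as variance components (`vc_formula`), mirroring a
  search in which they can be — and in the default data-generating
  process are — rejected.
- p-values use a residual-df t approximation
  (df = n − k_fixed − n_species), labeled approximate; this containment
  heuristic is coarser than a Satterthwaite computation but errs
  conservative at the scales used here.
- Pseudo-R²: marginal = Var(Xβ)/(Var(Xβ)+σ²_α+Σσ²_vc+σ²_ε);
  conditional adds all random components to the numerator. Var(Xβ) is
  the population variance of the fixed linear predictor over the frame.
- A constant response is returned as the exact degenerate fit (slopes 0,
  σ²_ε = 0) rather than handed to the optimizer.
- Optimizer: BFGS with Powell and Nelder-Mead fallbacks; non-convergence
  raises rather than returning a half-fit.

## Synthetic generator: what it emulates, what it does not

Ground truth per unit is a Gaussian mixture, one component per
generation: the first-generation mean follows
`stage_intercept + slope·log(GDD) + species_intercept + unit_noise`;
later generations sit one generation-gap later with geometrically
decaying weights (the across-generation abundance split is config, not
inference). True 10%/50% DOYs are numeric inversions of the mixture CDF
(brentq, xtol 1e-6), cross-checked against the closed-form normal
quantile in the univoltine case to <0.01 day.

Default truth coefficients: stage intercepts 354/382/399/410/432 for
adult/pupa/larva/egg/migrant, slope −30 d per log-GDD-unit,
σ_species = 8 d, σ_unit = 10 d, generation gap 45 d, generation sd 10 d.
These give midsummer flight at 600–1200 accumulated degree-days, adult
overwinterers emerging first and migrants arriving last, and a
temperature effect strong enough to matter but not to swamp the stage
structure. Climate defaults produce that GDD range over the study
latitudes via a sinusoidal annual cycle (mean 12 °C, amplitude 14 °C,
peak DOY 200, diurnal range 10 °C, daily noise 2 °C) with a −1 °C per
degree latitude gradient.

Observation defaults: 4–5 sites per cell with lognormal(0, 0.5)
abundance multipliers; weekly visits; survey seasons that may start as
late as DOY 152 (many programs need not start before about June 1 — the
demo uses DOY 121 so early flyers are observable); seasonal totals
lognormal with median 800 (locally common) vs 250; incidental base rate
60 expected records per unit at full effort and detectability, thinned
by a piecewise-linear seasonal effort ramp (0.3 at DOY 1 rising to 1.0
at DOY 150) times a 2× weekend multiplier. Detectability is uniform
(0.4, 1]; confusability label-swaps are implemented but off by default.

Not emulated: geographic structure inside a cell (records are uniform in
the tile), multi-observer checklists, identification error in the survey
stream, range edges, and non-Gaussian skew in flight curves (a config
switch exists for mixture asymmetry via unequal component sds/weights,
not a skew family). Passing tests therefore demonstrate *estimator*
correctness and calibration under the stated generative assumptions —
they do not certify the estimators against real-data pathologies such as
spatially clustered effort or detection that covaries with abundance.

## Experiment scales

Chosen so a full test run and the acceptance script each stay in the
minutes range on one core: coverage studies use 200 units per stream in
the test suite (100/200 in the acceptance script) with B = 200 (survey)
and B = 500 (incidental); mixed-model recovery uses 100 replicates of
300 units and 30 species; the demo pipeline is 5 species × 4 cells × 3
years. Each sub-experiment draws from its own dedicated seed stream so
adding units to one experiment cannot silently change another's sample.

## Known limitations

- The survey bootstrap resamples visits, not sites; with few sites and
  strong between-site heterogeneity a cluster (site-level) bootstrap
  would be more defensible.
- GCV occasionally undersmooths sparse bimodal units; the AIC-style
  alternative is not implemented.
- The day-0 reference in simulation mode is derived from the truth table
  (earliest per-species true 10% DOY − 7); with real field-guide input
  the CSV is supplied by the user and the check is genuinely external.
- Persistently-earlier species detection requires ≥3 matched units and
  strict inequality in all of them; with 1–2 units per species the flag
  is never raised.
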