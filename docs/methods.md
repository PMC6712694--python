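# Methods

This note documents the models, the synthetic-data design, numerical choices
and known limitations of `actipattern`. It states no empirical result beyond
what the test suite and `scripts/acceptance.py` compute at run time.

## The problem

Time spent in accelerometer-derived intensity categories is the canonical
exposure description in physical-activity epidemiology. Whether described by
four traditional categories (sedentary / light / moderate / vigorous, Evenson
cut points 0–99 / 100–2295 / 2296–4011 / ≥4012 counts per minute) or by a
23-interval spectrum (0–99, 100–249, 250–499, 500–999, then 500-cpm steps to
≥10 000), the variables are doubly problematic for regression: adjacent
intensities are strongly positively correlated (activity is autocorrelated in
people), and the variables are *closed* — they sum to each participant's wear
time, so every minute gained in one bin is lost from another. Closure alone
makes normalised data exactly singular; multicollinearity remains even in
open (min/day) data. The package implements and contrasts the analytic
responses to this: ignore the other bins (bivariate), model jointly anyway
(MLR), transform to log-ratio coordinates first (clr for latent-variable
models, pivot ilr for regression), or model the collinearity directly with
latent variables (PLS multivariate pattern analysis).

## Epoch processing (actigraphy)

1-s vertical-axis counts are restricted to 06:00–23:59, runs of ≥3600
consecutive zero-count seconds are non-wear (zero tolerance for interruptions;
spike allowances deliberately not implemented), a day is valid at ≥480 wear
minutes, a participant at ≥4 valid days. Each wear second is classified by
`60 × counts` against cpm cut points, intervals closed-left / open-right, the
last unbounded — the standard scaling when cpm thresholds are applied to 1-s
epochs. Daily bin seconds / 60 are averaged over valid days (arithmetic mean;
partial first/last calendar days are treated like any other). Per day,
bin seconds sum to wear seconds exactly, by construction. No weekend-day
requirement is imposed on the 4 valid days.

## Composite cardiometabolic score (healthscore)

Six indicators — systolic BP, triglycerides, TC:HDL, HOMA
(glucose[mmol/L] × insulin / 22.5), waist:height, Andersen shuttle-run
distance — are each residualised on sex (indicator) and age (years) by least
squares over the full analytic sample, z-scored (sample SD, ddof 1), the
Andersen z negated (fitness is protective), and averaged. The adjustment
model is plain OLS; nothing fancier is warranted by a two-covariate
adjustment. `insulin_units` selects whether the insulin column is consumed
as-is (`pmol`) or first converted pmol/L → mU/L by /6.945 (`mU`): published
cohort tables are inconsistent about which scale the /22.5 constant is
applied to, and the two conventions differ by that factor, so the choice is
explicit rather than guessed. Friedewald LDL (TC − HDL − TG/2.2, mmol/L) is
computed for description only and flagged, not refused, at TG ≥ 4.5 mmol/L.

## Compositional machinery (coda)

Closure divides by the row sum; zeros are first repaired by multiplicative
replacement with δ = min(1/60 min, 0.65 × the column's smallest nonzero
value), shrinking the positive parts proportionally — high spectrum bins
genuinely contain structural zeros and log-ratios are undefined at zero. δ is
configurable; no printed result of any cohort disambiguates the choice, so it
is a package default, logged with every replacement. clr subtracts the mean
log; pivot ilr uses `z_i = √((D−i)/(D−i+1)) ln(x_i / g(x_{i+1..D}))`. The D
"all-first" permutations are cyclic rotations: the pivoted bin moves to the
front, the rest keep their original cyclic order (only the leading position
is specified by the construction; the cyclic choice is ours). Isometry
(‖ilr‖ = ‖clr‖ per observation) is asserted to 1e-10 in tests; scale
invariance means min/day and proportions of wear time give identical
coordinates.

## PLS, target projection, selectivity ratios (patterns)

PLS1 by NIPALS on centred, unit-variance X and y: deterministic, no random
initialisation, tolerant of rank deficiency (duplicated columns receive equal
coefficients). With as many components as full-rank predictors it reproduces
OLS to 1e-8, which the tests check against an independent normal-equations
solve and against scikit-learn's `PLSRegression`.

Component count: Monte Carlo cross-validation with 1000 repetitions of
random 50/50 train/validation splits (library default; tests use fewer
repetitions). The chosen count is the smallest whose mean held-out RMSEP is
within one standard error of the minimum — a parsimony rule chosen because it
is reproducible and conservative; the resampling literature offers no single
canonical criterion. Q² = 1 − ΣPRESS/ΣTSS pooled over repetitions at the
chosen count, TSS about the training mean.

Target projection: `w_tp = b/‖b‖`, `t_tp = X_std w_tp`,
`p_tp = X_stdᵀ t_tp / (t_tpᵀ t_tp)`. The TP component's prediction equals the
full model's prediction identically (`X b = t_tp‖b‖`), asserted to 1e-10.
Selectivity ratio: `SR_j = sign(p_tp,j) · (p_tp,j² t_tpᵀt_tp) / ‖x_j‖²`, the
share of bin j's variance explained by the predictive component; bounded by
Cauchy–Schwarz, `|SR_j| ≤ 1` always. The variance ratio itself is
non-negative; the sign is carried from the TP loading so patterns display
direction of association. (The older chemometric convention divides explained
by *residual* variance; the explained/total form used here is the one that
keeps the statistic in [−1, 1].)

SR confidence intervals: the model (at the chosen component count) is refit
on each Monte Carlo training half, each refit's TP axis is sign-aligned to
the full-data axis (the axis is only defined up to sign), and the 2.5/97.5
percentiles across repetitions form the 95% CI; the point estimate comes from
the full data and the band is widened, if needed, to contain it. Percentile
half-sample intervals are mildly conservative for null variables — measured
coverage of truly null bins in the acceptance run is a few points above the
nominal 95%.

MLR uses statsmodels OLS with t-based 95% CIs. The design (with intercept)
is rejected with an explicit `SingularityError` when its column-normalised
condition number exceeds 1e10 — closed data with an intercept always trips
this, which is precisely the methodological point the comparison
demonstrates; min/day data are merely ill-conditioned and fit with visibly
unstable coefficients. ilr-MLR fits all D permutations and reports each bin's
first-pivot-coordinate coefficient; all D fits span the same coordinate
subspace, so their fitted values agree to 1e-8 (tested).

## Synthetic cohort generator (simulate)

The generator defines the study conditions for every calibration and
acceptance run; its defaults were fixed once and are not tuned per test.

- n = 841 participants; wear time ~ N(795, 56²) min/day, floored at 25% of
  the mean (cohort-scale values for 10-year-olds wearing the device ~13 h).
- Active-bin minutes: `exp(log_mean_j + λ_j F_i + e_ij)` with one shared
  activity factor `F_i ~ N(0,1)` and an AR(1) perturbation across adjacent
  bins. Defaults: `log_mean` linearly decaying 3.6 → −4.2 across the 22
  active bins (≈ 37 min/day in the lightest bin down to ~0.015 min/day in
  the top bin), λ = 0.35, AR ρ = 0.85, innovation SD 0.6. These were
  calibrated, once, to the qualitative correlation geometry of cohort
  accelerometry: adjacent-bin r ≈ 0.8–0.9, far-apart active bins ≈ 0.3,
  sedentary negatively correlated with everything.
- The sedentary bin is wear time minus active time (with proportional shrink
  of active bins in the rare case they exceed wear time), enforcing exact
  closure and the negative sedentary correlation in one mechanism.
- Outcome: `y = z(X)·β + ε`, effects β in SD units on the *standardized*
  bins. The default signature is +0.1 for sedentary, zero through the
  light/moderate range, and a linear ramp to −0.4 for the top vigorous bins.
  Residual SD defaults to 4.5, calibrated once so that the cross-validated
  explained variance of the multivariate model lands near 20% — the
  magnitude such cohorts report — rather than the implausibly strong fits a
  unit residual would give. The calibration targets the 23-bin spectrum
  description; with the 4-bin traditional scheme the same signature yields a
  much weaker planted signal.
- `attach_panel` optionally dresses the outcome up as a full participant
  table (realistic locations/scales, sex and age signal-free) so the
  composite-score stage can be exercised end to end.

What the generator does **not** emulate: seasonal/weekday structure, device
artifacts, triaxial signals, measurement error in the health panel, school
clustering, and any nonlinearity of the true dose–response. Passing tests
therefore demonstrate correctness and calibration of the *methods* under a
known linear signature with realistic correlation geometry — not that any
particular cohort finding is true.

## Determinism and seeds

Every stochastic step consumes a `numpy.random.default_rng` seed. The
comparison driver fans a master seed out to stage seeds by fixed affine
offsets (mod 2³¹−1) so each stage is independently reproducible; identical
configuration implies byte-identical outputs, asserted in tests.

## Problem sizes

Library defaults follow the full protocol (1000 Monte Carlo repetitions for
component selection and CIs; n = 841). The test and acceptance runs scale
some repetitions down (60–300 Monte Carlo repetitions, 150–220 calibration
replicates, cohorts of 160–841) — sizes chosen so the whole suite completes
in a few minutes while keeping Monte Carlo error well inside the asserted
margins.

## Known limitations

- Stochastic properties of the generator (sign recovery, pattern agreement,
  CI coverage) are distributional: individual seeds can fall just outside a
  point threshold, so they are asserted over 20-seed panels or replicate
  batches with explicit pass fractions.
- The ilr permutation scheme reports only first-pivot coefficients; full
  balance/sequential-binary-partition analyses are out of scope.
- Zero replacement is a modelling choice; results for the highest spectrum
  bins are sensitive to δ when zeros are frequent.
- The composite score's components are equally weighted; no attempt is made
  to validate the score against clinical endpoints.
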