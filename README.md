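# actipattern

Analysis pipeline for relating the **accelerometer-derived physical-activity
intensity spectrum** to a **composite cardiometabolic health score**, built to
compare — on identical data — the analytic approaches used in physical-activity
epidemiology when the explanatory variables are strongly multicollinear and
*closed* (per child, minutes across intensity bins sum exactly to accelerometer
wear time):

1. bivariate Pearson correlations per intensity bin,
2. multiple linear regression (MLR) on raw minutes/day,
3. MLR on isometric log-ratio (ilr, pivot-coordinate) transformed data,
4. multivariate pattern analysis (PLS regression with target projection and
   selectivity ratios) on raw data, and
5. the same multivariate pattern analysis on centred log-ratio (clr) data.

It is aimed at researchers in time-use and physical-activity epidemiology who
want to see, concretely, how closure and multicollinearity distort each
approach — and at anyone who needs a tested implementation of PLS target
projection with resampled selectivity-ratio confidence intervals.

## The statistics in brief

With intensity bins `x_1 … x_D` (min/day) and outcome `y` (a composite
cardiometabolic risk score, higher = worse):

- **Closure.** `Σ_j x_ij = wear time_i`. Normalising to proportions makes the
  design exactly singular (with only two behaviours, `r = −1`); MLR on such
  data must and does fail (`SingularityError`).
- **clr:** `clr_j(x) = ln x_j − (1/D) Σ_k ln x_k` — symmetric, still singular.
- **ilr pivot coordinates:**
  `z_i = √((D−i)/(D−i+1)) · ln( x_i / g(x_{i+1..D}) )`, `i = 1..D−1`, with `g`
  the geometric mean. The transform is repeated D times so that each bin leads
  once; its first-coordinate coefficient is that bin's reported effect.
- **PLS1 (NIPALS)** on standardized variables builds orthogonal components
  maximizing covariance with `y`; the component count is chosen by **Monte
  Carlo cross-validation** (1000 random 50/50 splits, one-standard-error rule
  on held-out RMSEP). **Target projection** compresses the model onto the
  single component `t = X·b/‖b‖` along the regression vector `b`, and the
  **selectivity ratio** of bin `j` is
  `SR_j = sign(p_tp,j) · explained_j / total_j ∈ [−1, 1]`,
  its variance explained by that component over its total variance, signed by
  the target-projection loading. 95% CIs come from the same Monte Carlo
  half-sample machinery.

The package also contains the full upstream pipeline: 1-s epoch processing
(06:00–23:59 restriction, ≥60-min zero-run non-wear detection, ≥8 h/day and
≥4 days validity, Evenson cut points, the 23-bin spectrum), the composite
score (mean of six sex/age-adjusted z-scores: systolic BP, triglycerides,
TC:HDL, HOMA, waist:height, reversed Andersen shuttle-run distance), and a
**synthetic cohort generator** that reproduces the data geometry (shared
activity factor, distance-decaying bin correlations, anti-correlated sedentary
bin, exact closure, planted intensity–outcome signature) so every stage is
verifiable without access to cohort data.

## Worked example

```python
from actipattern import SyntheticConfig, generate_spectrum_dataset, run_comparison

data = generate_spectrum_dataset(SyntheticConfig(seed=1))   # 841 children, 23 bins
report = run_comparison(data.profiles, data.outcome, {"reps": 1000, "seed": 1})
for tag, pat in report.patterns.items():
    print(f"{tag:10s} R2={pat.model_r2:.3f} Q2={pat.cv_q2:.3f}")
print("clr distortion: mean |Δr| = %.3f, sign flips = %d"
      % (report.correlation_report.mean_abs_change,
         report.correlation_report.n_sign_flips))
```

prints (bivariate has no model R²):

```
bivariate  R2=nan Q2=nan
mlr_raw    R2=0.283 Q2=nan
mlr_ilr    R2=0.195 Q2=nan
mpa_raw    R2=0.267 Q2=0.257
mpa_clr    R2=0.184 Q2=0.126
clr distortion: mean |Δr| = 0.526, sign flips = 149
```

Read: on a cohort with a planted signature (null effects at low intensities,
increasingly protective vigorous activity), all four models explain 18–28% of
the outcome variance, but their per-bin *patterns* differ sharply — the MLR
coefficients fluctuate with wide CIs, while the selectivity-ratio pattern of
the multivariate pattern analysis tracks the planted signature; and the clr
transform changes the sign of 149 of the 253 bin-pair correlations
(`correlations_raw.csv` vs `correlations_clr.csv` in a rendered report show
which).

The same pipeline is scriptable from a shell:

```bash
actipattern simulate spectrum --seed 1 --n 841 --with-panel --out sim/
actipattern score --panel sim/panel.csv --out scores.csv
actipattern fit --profiles sim/profiles.csv --outcome scores.csv \
                --model mpa_raw --reps 1000 --seed 1 --out fit/
actipattern compare --seed 1 --out report/
```

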