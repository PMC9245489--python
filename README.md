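# omegadose

Dose-response analysis of food-frequency-questionnaire (FFQ) derived
omega-3 polyunsaturated fatty acid intake against binary partner-reported
outcomes, in the style of large pregnancy-cohort nutritional epidemiology.
The package covers the full analytic chain:

1. **FFQ intake engine** (`omegadose.ffq`) — per-item frequency × portion ×
   composition arithmetic to daily nutrient and energy totals.
2. **Energy adjustment** (`omegadose.energy`) — Willett's residual method on
   the log scale: regress log(intake + c) on log(energy + c), keep the
   residual, re-centre at mean log energy.
3. **Synthetic cohort generator** (`omegadose.cohort`) — pair records with a
   configurable intake model, covariates, centre random effects,
   MCAR/MAR missingness, and a **known ground-truth dose-response curve**
   so that every estimator can be validated by parameter recovery.
4. **Multiple imputation** (`omegadose.impute`) — chained equations
   (predictive-mean matching, logistic/multinomial/proportional-odds
   draws) and Rubin's-rules pooling with Barnard–Rubin degrees of freedom.
5. **Penalized-spline logistic GAMM** (`omegadose.gamm`) — cubic B-spline
   smooth of log intake with quantile knots, a second divided-difference
   penalty, recruitment-centre random intercepts fitted as a ridge block,
   penalized IRLS inner loop, and Laplace-approximate REML smoothing
   selection.
6. **Adjusted-prevalence curves** (`omegadose.curves`) — marginal
   standardisation over the observed covariate distribution with a ±1 SEM
   delta-method band, landmark extraction (minimum, percentile, band
   crossings) and Rubin pooling of curves across imputations.
7. **Sensitivity analyses** (`omegadose.sensitivity`) — E-values for
   unmeasured confounding, generalised variance inflation factors, and
   Cramér's V between categorical covariates.
8. **Pipeline + CLI** (`omegadose.pipeline`, `omegadose.cli`) — one seeded
   call from cohort generation to a YAML report whose bytes are fully
   reproducible from (config, seed).

## Worked example

Fit the dose-response curve on a synthetic cohort whose true curve is
U-shaped with a minimum at 2.2 g/day:

```python
import numpy as np
from omegadose import (
    CohortConfig, GroundTruthCurve, OutcomeSpec, adjusted_prevalence_curve,
    binarise_outcome, generate_cohort, select_smoothing,
)

config = CohortConfig(
    n_pairs=48065, seed=7, missingness_rates={},
    outcomes={"ipv": OutcomeSpec(0.124, GroundTruthCurve("quadratic", 2.2, curvature=0.3))},
)
pairs = generate_cohort(config).pairs

y = binarise_outcome(pairs["ipv_likert"]).to_numpy(float)
z = np.log(pairs["omega3_g_day"].to_numpy() + 0.005)
fit, trace = select_smoothing(z, y, pairs[["age", "income", "smoking", "psych_distress"]],
                              pairs["centre_id"].to_numpy())

curve = adjusted_prevalence_curve(fit, pairs["omega3_g_day"])
lm = curve.landmarks
print(f"minimum {100 * lm.min_value:.2f}% at {lm.min_location:.2f} g/day "
      f"({lm.min_percentile:.0f}th percentile)")
```

Typical output:

```
minimum 16.22% at 2.20 g/day (65th percentile)
```

The full pipeline — generate, energy-adjust, impute, fit, pool, report —
runs from one config:

```python
from omegadose import RunConfig, run_pipeline
report = run_pipeline(RunConfig(out_dir="run", n_pairs=3000, seed=5, m=2))
```

or from the shell: `omegadose run --n-pairs 3000 --seed 5 --out run`.
See `examples/` for six narrated scripts covering each stage.

## Testing

`tests/` holds ~190 property, oracle and calibration tests:

- hand-computable oracles for every authored estimator (penalized IRLS vs
  a generic optimiser, energy adjustment vs explicit least squares,
  Rubin's rules, GVIF vs 1/(1−R²) and R's `car::vif`, Cramér's V,
  quintile odds ratios vs contingency tables);
- limiting-case reductions (λ→∞ gives a straight line in log intake,
  σ²ᵤ→0 recovers the fixed-effects fit, zero missingness makes MI an
  identity);
- full-scale parameter recovery of the dose-response minimum over 20
  seeded cohorts of n = 48 065, plus a plateau-truth arm guarding against
  spurious post-minimum upturns;
- frequentist calibration of pooled confidence intervals under MCAR.

`docs/methods.md` documents the statistical model, its parameters and the
numerical design decisions.
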