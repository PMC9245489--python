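"""Sensitivity diagnostics: E-values, GVIF and Cramér's V.

The E-value asks how strong an unmeasured confounder would have to be to
explain away the observed prevalence ratio; GVIF checks that the forced-
entry covariates are not collinear; Cramér's V quantifies pairwise
association between categorical covariates.
"""

from omegadose import CohortConfig, generate_cohort
from omegadose.sensitivity import (
    cramers_v,
    design_terms_from_covariates,
    evalue_from_rr,
    gvif,
)

# E-value from a curve's maximum and minimum adjusted prevalence
for label, pmax, pmin in [("physical violence", 1.35, 0.76), ("emotional abuse", 17.69, 12.44)]:
    res = evalue_from_rr(pmax / pmin)
    print(f"{label}: prevalence ratio {res.rr:.2f} -> E-value {res.evalue:.2f}")

cohort = generate_cohort(CohortConfig(n_pairs=8000, seed=3, missingness_rates={}))
cov = cohort.pairs[["age", "bmi", "education", "income", "smoking", "alcohol"]]

design, terms = design_terms_from_covariates(cov)
print("\nGVIF per covariate term (1 = no collinearity):")
print(gvif(design, terms).round(3).to_string())

import pandas as pd

table = pd.crosstab(cohort.pairs["education"], cohort.pairs["income"]).to_numpy()
print(f"\nCramér's V, education vs income: {cramers_v(table):.3f}")
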