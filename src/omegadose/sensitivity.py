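"""Sensitivity and diagnostic statistics.

* E-value: the minimum strength of association, on the risk-ratio scale,
  that an unmeasured confounder would need with both exposure and outcome
  to fully explain away an observed risk ratio:
  ``E = RR + sqrt(RR * (RR - 1))`` (with RR < 1 first inverted).  Here the
  RR is formed directly from the maximum and minimum adjusted prevalence
  of the dose-response curve over its percentile range — no odds-ratio to
  risk-ratio conversion is involved.
* Generalised variance inflation factors (GVIF) for designs with
  multi-column categorical terms, via the determinant ratio of correlation
  submatrices; reported together with GVIF^(1/(2 df)).
* Cramér's V effect size for two-way contingency tables,
  ``V = sqrt(chi2 / (n * (min(r, c) - 1)))`` with the chi-square computed
  without continuity correction by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = ["EValueResult", "evalue_from_rr", "evalue_from_curve", "gvif", "cramers_v"]


@dataclass
class EValueResult:
    rr: float  # risk ratio on the >= 1 scale (inverted if the input was < 1)
    evalue: float
    source: str = ""


def evalue_from_rr(rr: float, source: str = "") -> EValueResult:
    """E-value for a risk ratio: RR + sqrt(RR (RR - 1)), after inverting RR < 1."""
    if not rr > 0:
        raise ValueError("risk ratio must be positive")
    rr_std = rr if rr >= 1.0 else 1.0 / rr
    e = rr_std + math.sqrt(rr_std * (rr_std - 1.0))
    return EValueResult(rr=rr_std, evalue=e, source=source)


def evalue_from_curve(curve) -> EValueResult:
    """E-value from the max/min adjusted prevalence of a CurveSummary."""
    prev = curve.grid["prevalence"].to_numpy()
    pmax, pmin = float(prev.max()), float(prev.min())
    rr = pmax / pmin
    return evalue_from_rr(
        rr, source=f"max/min adjusted prevalence {100 * pmax:.2f}%/{100 * pmin:.2f}%"
    )


def gvif(design: pd.DataFrame, terms: dict[str, list[str]]) -> pd.DataFrame:
    """Generalised VIF per term of a design matrix.

    ``design`` holds the numeric predictor columns (no intercept);
    ``terms`` maps each term name to its column names (a categorical term
    owns all its dummy columns).  Returns a frame with ``gvif``, ``df``
    and ``gvif_scaled`` = GVIF^(1/(2 df)), computed as

        GVIF_t = det(R_t) * det(R_-t) / det(R)

    on the correlation matrix R of the centred design.
    """
    cols = [c for t in terms.values() for c in t]
    if len(set(cols)) != len(cols):
        raise ValueError("terms share columns")
    missing = set(cols) - set(design.columns)
    if missing:
        raise ValueError(f"design lacks columns {sorted(missing)}")
    X = design[cols].to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant column in design")
    R = np.corrcoef(X, rowvar=False)
    det_R = np.linalg.det(R)
    if det_R < 1e-300:
        raise np.linalg.LinAlgError("rank-deficient design: correlation matrix singular")
    index = {c: i for i, c in enumerate(cols)}
    rows = []
    for name, tcols in terms.items():
        idx = [index[c] for c in tcols]
        rest = [i for i in range(len(cols)) if i not in idx]
        det_t = np.linalg.det(R[np.ix_(idx, idx)])
        det_rest = np.linalg.det(R[np.ix_(rest, rest)]) if rest else 1.0
        g = det_t * det_rest / det_R
        df = len(idx)
        rows.append(
            {"term": name, "gvif": g, "df": df, "gvif_scaled": g ** (1.0 / (2 * df))}
        )
    return pd.DataFrame(rows).set_index("term")


def design_terms_from_covariates(covariates: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Dummy-encode categorical covariates and group columns by term."""
    design = pd.get_dummies(covariates.astype("object"), drop_first=True, dtype=float)
    terms: dict[str, list[str]] = {}
    for col in covariates.columns:
        owned = [c for c in design.columns if c.startswith(f"{col}_")]
        if owned:
            terms[col] = owned
    return design, terms


def cramers_v(table, correction: bool = False) -> float:
    """Cramér's V for a two-way contingency table of nonnegative counts."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t < 0).any() or t.sum() <= 0:
        raise ValueError("table must hold nonnegative counts with positive total")
    n = t.sum()
    chi2 = chi2_contingency(t, correction=correction)[0]
    k = min(t.shape) - 1
    return math.sqrt(chi2 / (n * k))
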