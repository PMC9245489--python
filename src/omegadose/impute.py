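"""Multiple imputation by chained equations and Rubin's-rules pooling.

Missing covariate values are filled by cycling per-variable conditional
models (chained equations): each incomplete variable is regressed on all
other variables on its observed rows, and its missing rows are drawn from
the fitted model.  Per-variable methods follow the variable's type:

``continuous``
    predictive-mean matching (PMM): a Bayesian linear-regression draw
    produces predictions, and each missing row receives the observed value
    of one of its 5 nearest prediction neighbours;
``binary`` / ``categorical``
    (multinomial) logistic regression fitted on a bootstrap resample of
    the observed rows (the resample approximates parameter uncertainty),
    imputing by sampling from predicted class probabilities;
``ordinal``
    proportional-odds regression, same bootstrap scheme, falling back to
    multinomial logistic if the ordered fit fails.

Downstream estimates computed once per completed dataset are combined by
Rubin's rules with the Barnard-Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

__all__ = ["ImputationSpec", "PooledEstimate", "mice", "pool"]


@dataclass
class ImputationSpec:
    """Configuration of one chained-equations run."""

    m: int = 10
    n_iterations: int = 10
    methods: dict[str, str] = field(default_factory=dict)  # variable -> method override
    pmm_donors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least m=2 imputations")
        if self.n_iterations < 1:
            raise ValueError("need at least one sweep")


_KIND_TO_METHOD = {
    "continuous": "pmm",
    "binary": "logistic",
    "categorical": "multinomial",
    "ordinal": "ordinal",
}


def _encode_predictors(df: pd.DataFrame, schema: dict, exclude: str) -> np.ndarray:
    """Numeric predictor matrix from all variables except ``exclude``."""
    cols = []
    for name, spec in schema.items():
        if name == exclude or spec["kind"] in ("id", "cluster"):
            continue
        s = df[name]
        if spec["kind"] == "continuous":
            cols.append(s.to_numpy(float)[:, None])
        else:
            levels = spec["levels"]
            arr = s.to_numpy()
            cols.append(
                np.column_stack([(arr == lvl).astype(float) for lvl in levels[1:]])
            )
    if not cols:
        return np.zeros((len(df), 0))
    return np.hstack(cols)


def _bayes_linear_draw(Xo, yo, rng):
    """Posterior draw of (beta, sigma) under the noninformative prior."""
    n, p = Xo.shape
    Xo1 = np.hstack([np.ones((n, 1)), Xo])
    # small ridge guards against collinearity of dummy predictors
    XtX = Xo1.T @ Xo1 + 1e-8 * np.eye(p + 1)
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ (Xo1.T @ yo)
    resid = yo - Xo1 @ beta_hat
    df = max(n - p - 1, 1)
    sigma2 = resid @ resid / stats.chi2.rvs(df, random_state=rng)
    L = np.linalg.cholesky((XtX_inv + XtX_inv.T) / 2 * sigma2)
    beta = beta_hat + L @ rng.standard_normal(p + 1)
    return beta, math.sqrt(sigma2)


def _impute_pmm(df, name, miss, X, rng, donors):
    obs = ~miss
    Xo, yo = X[obs.to_numpy()], df.loc[obs, name].to_numpy(float)
    Xm = X[miss.to_numpy()]
    beta, _ = _bayes_linear_draw(Xo, yo, rng)
    pred_obs = np.hstack([np.ones((len(Xo), 1)), Xo]) @ beta
    pred_mis = np.hstack([np.ones((len(Xm), 1)), Xm]) @ beta
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    out = np.empty(len(pred_mis))
    k = min(donors, len(yo))
    for i, p in enumerate(pred_mis):
        j = np.searchsorted(sorted_pred, p)
        lo = max(0, j - k)
        hi = min(len(sorted_pred), j + k)
        cand = order[lo:hi]
        dist = np.abs(sorted_pred[lo:hi] - p)
        nearest = cand[np.argsort(dist, kind="stable")[:k]]
        out[i] = yo[rng.choice(nearest)]
    df.loc[miss, name] = out


def _impute_categorical(df, name, miss, X, rng, levels, ordinal=False):
    obs = (~miss).to_numpy()
    yo = df.loc[~miss, name].to_numpy()
    Xo, Xm = X[obs], X[miss.to_numpy()]
    # bootstrap the observed rows to propagate parameter uncertainty
    idx = rng.integers(0, len(yo), len(yo))
    yb, Xb = yo[idx], Xo[idx]
    present = pd.unique(yb)
    if len(present) < 2:
        df.loc[miss, name] = present[0]
        return
    proba = None
    classes = None
    if ordinal:
        proba, classes = _ordered_probs(Xb, yb, Xm, levels)
    if proba is None:
        model = LogisticRegression(max_iter=200, C=1e4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xb, yb)
        proba = model.predict_proba(Xm)
        classes = model.classes_
    cum = np.cumsum(proba, axis=1)
    u = rng.random(len(Xm))
    pick = (u[:, None] > cum).sum(axis=1)
    df.loc[miss, name] = np.asarray(classes)[np.minimum(pick, len(classes) - 1)]


def _ordered_probs(Xb, yb, Xm, levels):
    """Proportional-odds fit; returns (probs, classes) or (None, None) on failure."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    present = [lvl for lvl in levels if lvl in set(yb)]
    if len(present) < 3:
        return None, None
    codes = pd.Categorical(yb, categories=present, ordered=True).codes
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(codes, Xb, distr="logit")
            res = model.fit(method="bfgs", maxiter=200, disp=False)
        proba = res.model.predict(res.params, exog=Xm)
    except Exception:
        return None, None
    if not np.all(np.isfinite(proba)):
        return None, None
    return proba, np.asarray(present, dtype=object)


def mice(
    data: pd.DataFrame, schema: dict, spec: ImputationSpec | None = None
) -> list[pd.DataFrame]:
    """Chained-equations imputation -> list of ``m`` completed datasets.

    ``schema`` maps column name to ``{"kind": ..., "levels": [...]}`` as
    produced by ``Cohort.schema()``; only columns present in the schema
    participate (id/cluster columns are carried through untouched).
    Observed cells are never modified.  With no missing cells the result is
    ``m`` identical copies of the input.
    """
    spec = spec or ImputationSpec()
    rng = np.random.default_rng(spec.seed)
    work_schema = {k: v for k, v in schema.items() if k in data.columns}
    incomplete = [
        name
        for name, s in work_schema.items()
        if s["kind"] not in ("id", "cluster") and data[name].isna().any()
    ]
    for name in incomplete:
        if data[name].isna().all():
            raise ValueError(f"variable {name!r} is fully missing and cannot be imputed")
        method = spec.methods.get(name, _KIND_TO_METHOD[work_schema[name]["kind"]])
        if method not in {"pmm", "norm", "logistic", "multinomial", "ordinal"}:
            raise ValueError(f"unknown imputation method {method!r} for {name!r}")

    if not incomplete:
        return [data.copy() for _ in range(spec.m)]

    masks = {name: data[name].isna() for name in incomplete}
    completed = []
    for _ in range(spec.m):
        df = data.copy()
        # random-draw initialisation from the observed marginal
        for name in incomplete:
            obs_vals = df.loc[~masks[name], name].to_numpy()
            df.loc[masks[name], name] = rng.choice(obs_vals, size=int(masks[name].sum()))
        for _sweep in range(spec.n_iterations):
            for name in incomplete:
                s = work_schema[name]
                method = spec.methods.get(name, _KIND_TO_METHOD[s["kind"]])
                X = _encode_predictors(df, work_schema, exclude=name)
                if method == "pmm":
                    _impute_pmm(df, name, masks[name], X, rng, spec.pmm_donors)
                elif method == "norm":
                    _impute_norm(df, name, masks[name], X, rng)
                else:
                    _impute_categorical(
                        df, name, masks[name], X, rng, s.get("levels"), ordinal=method == "ordinal"
                    )
        completed.append(df)
    return completed


def _impute_norm(df, name, miss, X, rng):
    """Linear-Gaussian draw (no matching): posterior predictive normal."""
    obs = ~miss
    Xo, yo = X[obs.to_numpy()], df.loc[obs, name].to_numpy(float)
    Xm = X[miss.to_numpy()]
    beta, sigma = _bayes_linear_draw(Xo, yo, rng)
    pred = np.hstack([np.ones((len(Xm), 1)), Xm]) @ beta
    df.loc[miss, name] = pred + sigma * rng.standard_normal(len(pred))


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m point estimates and variances."""

    point: float
    within_var: float
    between_var: float
    total_var: float
    m: int
    df: float

    @property
    def se(self) -> float:
        return math.sqrt(self.total_var)

    def ci(self, alpha: float = 0.05) -> tuple[float, float]:
        q = stats.t.ppf(1 - alpha / 2, self.df) if math.isfinite(self.df) else stats.norm.ppf(
            1 - alpha / 2
        )
        return self.point - q * self.se, self.point + q * self.se


def pool(estimates, variances, df_com: float | None = None) -> PooledEstimate:
    """Rubin's rules: T = W + (1 + 1/m) B, Barnard-Rubin degrees of freedom.

    ``df_com`` is the complete-data residual degrees of freedom; when
    omitted, the large-sample (infinite) value is used.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.ndim != 1 or est.shape != var.shape:
        raise ValueError("estimates and variances must be 1-d and equal length")
    m = len(est)
    if m < 2:
        raise ValueError("pooling requires at least two imputations")
    if (var < 0).any():
        raise ValueError("variances must be nonnegative")
    point = float(est.mean())
    W = float(var.mean())
    B = float(est.var(ddof=1))
    T = W + (1 + 1 / m) * B

    if B == 0.0:
        df = float("inf")
    else:
        r = (1 + 1 / m) * B
        df_old = (m - 1) * (1 + W / r) ** 2
        if df_com is None or not math.isfinite(df_com):
            df = df_old
        else:
            gamma = r / T
            df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - gamma)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    return PooledEstimate(
        point=point, within_var=W, between_var=B, total_var=float(T), m=m, df=float(df)
    )
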