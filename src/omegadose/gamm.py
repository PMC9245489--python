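"""Penalized-spline logistic additive model with cluster random intercepts.

The central model of the pipeline is a logistic additive mixed model

    logit P(y_ij = 1) = x_ij' beta + f(z_ij) + u_j,   u_j ~ N(0, sigma2_u)

where ``z`` is log energy-adjusted intake, ``f`` a cubic penalized
regression spline (B-spline basis with quantile knots, second-order
divided-difference penalty at the Greville abscissae, sum-to-zero
constrained), ``x`` the forced-entry categorical confounder dummies and
``u_j`` a random intercept for each of the regional centres.  The random
intercept is handled in the standard mixed-model-as-penalty formulation:
centre indicator columns with a ridge penalty of precision ``1/sigma2_u``.

Fitting is by penalized iteratively reweighted least squares (PIRLS) with
step halving, maximising

    l(beta) - (lam/2) b_s' S b_s - 1/(2 sigma2_u) sum_j u_j^2 .

The smoothing parameter ``lam`` and variance component ``sigma2_u`` are
chosen in an outer loop by Laplace-approximate REML (grid search plus
golden-section refinement on log lam); AIC is available as an alternative
criterion.  The coefficient covariance is the Bayesian posterior
covariance ``(X'WX + P)^{-1}`` of the penalized fit, which is what the
Wald intervals and the prevalence-curve bands use.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import BSpline
from scipy.special import expit, logit
from scipy.stats import chi2, norm

__all__ = [
    "SplineBasis",
    "DoseResponseFit",
    "QuintileFit",
    "build_basis",
    "fit_gamm",
    "select_smoothing",
    "fit_quintiles",
    "smooth_wald_test",
    "GammConvergenceError",
]

_ETA_CLIP = 30.0
_W_FLOOR = 1e-10


class GammConvergenceError(RuntimeError):
    """Raised when PIRLS fails to converge or the fit separates."""


@dataclass
class SplineBasis:
    """Cubic B-spline basis with interior knots at data quantiles."""

    knots: np.ndarray  # full (padded) knot vector
    degree: int = 3
    penalty_order: int = 2

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    @property
    def interior_knots(self) -> np.ndarray:
        return self.knots[self.degree + 1 : -(self.degree + 1)]

    @property
    def range(self) -> tuple[float, float]:
        return float(self.knots[self.degree]), float(self.knots[-self.degree - 1])

    def design(self, x) -> np.ndarray:
        """Dense basis matrix; x clipped to the knot range (no extrapolation)."""
        lo, hi = self.range
        x = np.clip(np.asarray(x, dtype=float), lo, hi)
        m = BSpline.design_matrix(x, self.knots, self.degree, extrapolate=False)
        return np.asarray(m.todense())

    def greville(self) -> np.ndarray:
        """Greville abscissae: the knot averages each coefficient acts at."""
        k, d = self.knots, self.degree
        return np.array([k[i + 1 : i + d + 1].mean() for i in range(self.n_basis)])

    def penalty(self) -> np.ndarray:
        """Difference penalty matrix D'D on the basis coefficients.

        ``D`` takes ``penalty_order``-th *divided* differences at the
        Greville abscissae rather than plain coefficient differences: with
        unequal (quantile) knots this keeps the penalty null space equal to
        the polynomials of degree < penalty_order in x, so heavy smoothing
        reduces a second-order-penalized smooth to a straight line in x.
        With equally spaced knots it coincides with the classical
        difference penalty up to a constant factor absorbed by lambda.
        """
        t = self.greville()
        D = np.eye(self.n_basis)
        for m in range(1, self.penalty_order + 1):
            dt = t[m:] - t[:-m]
            D = np.diff(D, axis=0) / dt[:, None]
        return D.T @ D


def build_basis(
    log_intakes, n_basis: int = 10, degree: int = 3, penalty_order: int = 2
) -> SplineBasis:
    """Basis with interior knots at quantiles of the observed log intakes."""
    x = np.asarray(log_intakes, dtype=float)
    uniq = np.unique(x)
    if n_basis < penalty_order + 1:
        raise ValueError("n_basis must exceed the penalty order")
    if len(uniq) < n_basis:
        raise ValueError(f"need at least {n_basis} distinct values, got {len(uniq)}")
    n_interior = n_basis - degree - 1
    if n_interior > 0:
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(uniq, probs)
    else:
        interior = np.array([])
    lo, hi = float(uniq[0]), float(uniq[-1])
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    return SplineBasis(knots=knots, degree=degree, penalty_order=penalty_order)


def _sum_to_zero_constraint(B: np.ndarray) -> np.ndarray:
    """Orthonormal null-space basis Z of the column-sum constraint 1'B b = 0."""
    c = B.sum(axis=0, keepdims=True)
    # SVD of the 1 x p constraint; right singular vectors 2..p span its null space
    _, _, vt = np.linalg.svd(c, full_matrices=True)
    return vt[1:].T


def _dummies(covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((0, 0)), []
    d = pd.get_dummies(covariates.astype("object"), drop_first=True, dtype=float)
    return d.to_numpy(), list(d.columns)


@dataclass
class DoseResponseFit:
    """Converged penalized logistic mixed fit and everything needed downstream."""

    beta: np.ndarray
    cov: np.ndarray  # (X'WX + P)^-1, Bayesian posterior covariance
    basis: SplineBasis
    constraint: np.ndarray  # Z mapping constrained -> raw spline coefficients
    lam: float
    sigma2_u: float
    slice_fixed: slice
    slice_spline: slice
    slice_centre: slice
    column_names: list[str]
    centre_levels: np.ndarray
    design_row_mean: np.ndarray
    row_offsets: np.ndarray  # per-row fixed + centre linear predictor (no spline)
    edf_smooth: float
    edf_total: float
    loglik: float
    deviance: float
    laml: float
    n_obs: int
    n_iter: int
    converged: bool
    separation: bool

    @property
    def spline_coefs(self) -> np.ndarray:
        return self.beta[self.slice_spline]

    @property
    def random_intercepts(self) -> np.ndarray:
        return self.beta[self.slice_centre]

    def spline_values(self, log_intake) -> np.ndarray:
        """Centred smooth f(z) on the log-intake axis."""
        return self.basis.design(log_intake) @ self.constraint @ self.spline_coefs

    def mean_design_row(self, log_intake: float) -> np.ndarray:
        """Population-mean design row with the smooth evaluated at one intake."""
        row = self.design_row_mean.copy()
        bs = self.basis.design([log_intake]) @ self.constraint
        row[self.slice_spline] = bs[0]
        return row

    def save(self, stem) -> None:
        """Serialise as <stem>.yaml (metadata) + <stem>.npz (arrays)."""
        stem = Path(stem)
        np.savez(
            stem.with_suffix(".npz"),
            beta=self.beta,
            cov=self.cov,
            knots=self.basis.knots,
            constraint=self.constraint,
            design_row_mean=self.design_row_mean,
            row_offsets=self.row_offsets,
            centre_levels=self.centre_levels,
        )
        meta = {
            "lam": float(self.lam),
            "sigma2_u": float(self.sigma2_u),
            "degree": self.basis.degree,
            "penalty_order": self.basis.penalty_order,
            "column_names": self.column_names,
            "slices": {
                "fixed": [self.slice_fixed.start, self.slice_fixed.stop],
                "spline": [self.slice_spline.start, self.slice_spline.stop],
                "centre": [self.slice_centre.start, self.slice_centre.stop],
            },
            "edf_smooth": float(self.edf_smooth),
            "edf_total": float(self.edf_total),
            "loglik": float(self.loglik),
            "deviance": float(self.deviance),
            "laml": float(self.laml),
            "n_obs": int(self.n_obs),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "separation": bool(self.separation),
        }
        with open(stem.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)

    @classmethod
    def load(cls, stem) -> "DoseResponseFit":
        stem = Path(stem)
        arrays = np.load(stem.with_suffix(".npz"))
        with open(stem.with_suffix(".yaml")) as fh:
            meta = yaml.safe_load(fh)
        basis = SplineBasis(
            knots=arrays["knots"], degree=meta["degree"], penalty_order=meta["penalty_order"]
        )
        s = meta["slices"]
        return cls(
            beta=arrays["beta"],
            cov=arrays["cov"],
            basis=basis,
            constraint=arrays["constraint"],
            lam=meta["lam"],
            sigma2_u=meta["sigma2_u"],
            slice_fixed=slice(*s["fixed"]),
            slice_spline=slice(*s["spline"]),
            slice_centre=slice(*s["centre"]),
            column_names=meta["column_names"],
            centre_levels=arrays["centre_levels"],
            design_row_mean=arrays["design_row_mean"],
            row_offsets=arrays["row_offsets"],
            edf_smooth=meta["edf_smooth"],
            edf_total=meta["edf_total"],
            loglik=meta["loglik"],
            deviance=meta["deviance"],
            laml=meta["laml"],
            n_obs=meta["n_obs"],
            n_iter=meta["n_iter"],
            converged=meta["converged"],
            separation=meta["separation"],
        )


def _assemble(
    log_intake: np.ndarray,
    covariates: pd.DataFrame | None,
    centre_ids: np.ndarray | None,
    basis: SplineBasis,
):
    n = len(log_intake)
    B_raw = basis.design(log_intake)
    Z = _sum_to_zero_constraint(B_raw)
    Bc = B_raw @ Z
    Sc = Z.T @ basis.penalty() @ Z

    D, dummy_names = _dummies(covariates)
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    if D.size:
        blocks.append(D)
        names += dummy_names
    n_fixed = 1 + (D.shape[1] if D.size else 0)
    blocks.append(Bc)
    names += [f"spline_{k}" for k in range(Bc.shape[1])]

    if centre_ids is not None:
        centre_levels = np.unique(centre_ids)
        E = (np.asarray(centre_ids)[:, None] == centre_levels[None, :]).astype(float)
        blocks.append(E)
        names += [f"centre_{c}" for c in centre_levels]
    else:
        centre_levels = np.array([])

    X = np.hstack(blocks)
    sl_fixed = slice(0, n_fixed)
    sl_spline = slice(n_fixed, n_fixed + Bc.shape[1])
    sl_centre = slice(n_fixed + Bc.shape[1], X.shape[1])
    return X, names, Z, Sc, sl_fixed, sl_spline, sl_centre, centre_levels


def _penalty_matrix(p, sl_spline, sl_centre, Sc, lam, sigma2_u):
    P = np.zeros((p, p))
    P[sl_spline, sl_spline] = lam * Sc
    n_centre = sl_centre.stop - sl_centre.start
    if n_centre:
        P[sl_centre, sl_centre] = np.eye(n_centre) / sigma2_u
    return P


def _bernoulli_loglik(y, eta):
    # numerically stable: -log(1 + exp(-(2y-1) eta))
    s = (2 * y - 1) * eta
    return float(-np.sum(np.logaddexp(0.0, -s)))


def _pirls(X, y, P, beta0=None, max_iter=200, tol=1e-8):
    """Penalized IRLS with step halving; returns (beta, H, loglik, n_iter, converged)."""
    n, p = X.shape
    if beta0 is None:
        beta = np.zeros(p)
        pbar = float(np.clip(np.mean(y), 1e-4, 1 - 1e-4))
        beta[0] = logit(pbar)
    else:
        beta = beta0.copy()

    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    pen_dev = -2.0 * _bernoulli_loglik(y, eta) + beta @ P @ beta
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), _W_FLOOR)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        H = X.T @ Xw
        rhs = X.T @ (w * z)
        try:
            beta_new = np.linalg.solve(H + P, rhs)
        except np.linalg.LinAlgError as err:
            raise GammConvergenceError(f"singular penalized system at iteration {it}") from err

        # step halving on the penalized deviance
        step = 1.0
        for _ in range(30):
            cand = beta + step * (beta_new - beta)
            eta_c = np.clip(X @ cand, -_ETA_CLIP, _ETA_CLIP)
            pen_dev_c = -2.0 * _bernoulli_loglik(y, eta_c) + cand @ P @ cand
            if pen_dev_c <= pen_dev + 1e-12:
                break
            step *= 0.5
        else:
            converged = True  # no further descent possible
            break
        beta, eta = cand, eta_c
        if abs(pen_dev - pen_dev_c) < tol * (abs(pen_dev_c) + 0.1):
            pen_dev = pen_dev_c
            converged = True
            break
        pen_dev = pen_dev_c

    mu = expit(eta)
    w = np.maximum(mu * (1.0 - mu), _W_FLOOR)
    H = X.T @ (X * w[:, None])
    return beta, H, _bernoulli_loglik(y, eta), it, converged


def _log_pseudo_det(Sc, lam, n_centre, sigma2_u):
    """log pseudo-determinant of the penalty over its penalized range."""
    eig = np.linalg.eigvalsh(Sc)
    pos = eig[eig > eig.max() * 1e-10]
    out = len(pos) * math.log(lam) + float(np.sum(np.log(pos)))
    rank = len(pos)
    if n_centre:
        out += n_centre * math.log(1.0 / sigma2_u)
        rank += n_centre
    return out, rank


def fit_gamm(
    log_intake,
    y,
    covariates: pd.DataFrame | None,
    centre_ids,
    lam: float,
    sigma2_u: float,
    n_basis: int = 10,
    basis: SplineBasis | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    beta0: np.ndarray | None = None,
) -> DoseResponseFit:
    """Inner fit at fixed smoothing parameter and variance component.

    ``sigma2_u = 0`` (or ``centre_ids=None``) drops the random-intercept
    block entirely, giving the fixed-effects penalized logistic fit.
    """
    log_intake = np.asarray(log_intake, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if lam <= 0:
        raise ValueError("lam must be positive")
    if sigma2_u < 0:
        raise ValueError("sigma2_u must be nonnegative")
    if sigma2_u == 0:
        centre_ids = None

    basis = basis or build_basis(log_intake, n_basis=n_basis)
    X, names, Z, Sc, sl_f, sl_s, sl_c, centre_levels = _assemble(
        log_intake, covariates, centre_ids, basis
    )
    P = _penalty_matrix(X.shape[1], sl_s, sl_c, Sc, lam, max(sigma2_u, 1e-300))

    beta, H, loglik, n_iter, converged = _pirls(X, y, P, beta0=beta0, max_iter=max_iter, tol=tol)
    separation = bool(np.abs(np.clip(X @ beta, None, None)).max() >= _ETA_CLIP - 1e-6)
    if not converged:
        warnings.warn("PIRLS did not reach the convergence tolerance", RuntimeWarning)

    V = np.linalg.inv(H + P)
    F = V @ H  # effective-degrees-of-freedom matrix
    edf_total = float(np.trace(F))
    edf_smooth = float(np.trace(F[sl_s, sl_s]))

    pen = float(beta @ P @ beta)
    sign, logdet_Hp = np.linalg.slogdet(H + P)
    if sign <= 0:
        raise GammConvergenceError("penalized Hessian not positive definite")
    logdet_P, rank_P = _log_pseudo_det(Sc, lam, sl_c.stop - sl_c.start, max(sigma2_u, 1e-300))
    # negative Laplace-approximate restricted marginal likelihood
    laml = -(loglik - 0.5 * pen) + 0.5 * logdet_Hp - 0.5 * logdet_P - 0.5 * rank_P * math.log(
        2 * math.pi
    )

    return DoseResponseFit(
        beta=beta,
        cov=V,
        basis=basis,
        constraint=Z,
        lam=lam,
        sigma2_u=sigma2_u,
        slice_fixed=sl_f,
        slice_spline=sl_s,
        slice_centre=sl_c,
        column_names=names,
        centre_levels=centre_levels,
        design_row_mean=X.mean(axis=0),
        row_offsets=X[:, sl_f] @ beta[sl_f]
        + (X[:, sl_c] @ beta[sl_c] if sl_c.stop > sl_c.start else 0.0),
        edf_smooth=edf_smooth,
        edf_total=edf_total,
        loglik=loglik,
        deviance=-2.0 * loglik,
        laml=laml,
        n_obs=len(y),
        n_iter=n_iter,
        converged=converged,
        separation=separation,
    )


def _criterion_value(fit: DoseResponseFit, criterion: str) -> float:
    if criterion == "reml":
        return fit.laml
    if criterion == "aic":
        return fit.deviance + 2.0 * fit.edf_total
    raise ValueError(f"unknown smoothing criterion {criterion!r}")


def select_smoothing(
    log_intake,
    y,
    covariates: pd.DataFrame | None,
    centre_ids,
    n_basis: int = 10,
    criterion: str = "reml",
    lam_grid=None,
    sigma2_grid=None,
    refine_iter: int = 12,
) -> tuple[DoseResponseFit, pd.DataFrame]:
    """Outer smoothing selection: grid search + golden-section refinement.

    Returns the fit at the selected ``(lam, sigma2_u)`` and the criterion
    trace over the search.
    """
    log_intake = np.asarray(log_intake, dtype=float)
    basis = build_basis(log_intake, n_basis=n_basis)
    if lam_grid is None:
        lam_grid = np.logspace(-2, 6, 21)
    if sigma2_grid is None:
        sigma2_grid = (0.001, 0.01, 0.05, 0.15, 0.4) if centre_ids is not None else (0.0,)

    rows = []
    best = None
    n_failed = 0
    for s2 in sigma2_grid:
        beta0 = None
        for lam in lam_grid:
            try:
                fit = fit_gamm(
                    log_intake, y, covariates, centre_ids, lam, s2, basis=basis, beta0=beta0
                )
            except GammConvergenceError:
                n_failed += 1
                continue
            beta0 = fit.beta
            crit = _criterion_value(fit, criterion)
            rows.append({"lam": lam, "sigma2_u": s2, "criterion": crit})
            if best is None or crit < best[0]:
                best = (crit, fit)
    if best is None:
        raise GammConvergenceError(f"all {n_failed} fits in the smoothing search failed")

    # golden-section refinement on log lam at the selected sigma2_u
    _, fit = best
    s2 = fit.sigma2_u
    lam_grid = np.asarray(lam_grid)
    i = int(np.argmin(np.abs(np.log(lam_grid) - math.log(fit.lam))))
    lo = math.log(lam_grid[max(i - 1, 0)])
    hi = math.log(lam_grid[min(i + 1, len(lam_grid) - 1)])
    invphi = (math.sqrt(5.0) - 1.0) / 2.0

    def evaluate(loglam):
        f = fit_gamm(log_intake, y, covariates, centre_ids, math.exp(loglam), s2, basis=basis, beta0=fit.beta)
        c = _criterion_value(f, criterion)
        rows.append({"lam": math.exp(loglam), "sigma2_u": s2, "criterion": c})
        return c, f

    a, b = lo, hi
    c_pt = b - invphi * (b - a)
    d_pt = a + invphi * (b - a)
    fc, fit_c = evaluate(c_pt)
    fd, fit_d = evaluate(d_pt)
    for _ in range(refine_iter):
        if fc < fd:
            b, d_pt, fd, fit_d = d_pt, c_pt, fc, fit_c
            c_pt = b - invphi * (b - a)
            fc, fit_c = evaluate(c_pt)
        else:
            a, c_pt, fc, fit_c = c_pt, d_pt, fd, fit_d
            d_pt = a + invphi * (b - a)
            fd, fit_d = evaluate(d_pt)
    refined = fit_c if fc < fd else fit_d
    crit_refined = min(fc, fd)
    if crit_refined < best[0]:
        fit = refined

    trace = pd.DataFrame(rows)
    return fit, trace


def smooth_wald_test(fit: DoseResponseFit) -> tuple[float, float, float]:
    """Wald test of the whole smooth term: (statistic, df, p-value).

    Uses the Bayesian covariance of the spline block with the test degrees
    of freedom set to the rounded effective degrees of freedom of the
    smooth (minimum 1); mildly conservative under heavy penalization.
    """
    b = fit.spline_coefs
    V = fit.cov[fit.slice_spline, fit.slice_spline]
    stat = float(b @ np.linalg.pinv(V) @ b)
    df = max(1.0, round(fit.edf_smooth))
    return stat, df, float(chi2.sf(stat, df))


@dataclass
class QuintileFit:
    """Exposure recoded into quintiles: per-quintile odds ratios vs a reference."""

    cutpoints: np.ndarray  # inner boundaries on the exposure scale
    reference: int  # 1-based quintile index
    table: pd.DataFrame = field(repr=False)  # quintile, or, lo, hi, log_or, se
    sigma2_u: float = 0.0

    def odds_ratio(self, quintile: int) -> float:
        return float(self.table.set_index("quintile").loc[quintile, "or"])


def quintile_assign(exposure) -> tuple[np.ndarray, np.ndarray]:
    """Quintile index 1..5 by rank (stable, ties broken by input order).

    Boundaries are left-closed: the lowest fifth of ranks is quintile 1.
    Returns (assignments, inner cut points on the exposure scale).
    """
    x = np.asarray(exposure, dtype=float)
    n = len(x)
    if len(np.unique(x)) < 5:
        raise ValueError("exposure needs at least 5 distinct values")
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    q = np.minimum(ranks * 5 // n, 4) + 1
    cuts = np.array([x[order[(n * k) // 5]] for k in range(1, 5)])
    return q, cuts


def fit_quintiles(
    exposure,
    y,
    covariates: pd.DataFrame | None,
    centre_ids,
    reference: int = 1,
    sigma2_u: float | None = None,
    alpha: float = 0.05,
) -> QuintileFit:
    """Logistic mixed fit with the exposure replaced by quintile indicators.

    The same forced-entry covariates and centre random intercept are kept;
    odds ratios with Wald CIs are reported for each non-reference quintile
    (the reference has OR 1 by construction).  If ``sigma2_u`` is None it
    is selected by the Laplace-REML criterion over a small grid.
    """
    if reference not in range(1, 6):
        raise ValueError("reference quintile must be in 1..5")
    y = np.asarray(y, dtype=float)
    q, cuts = quintile_assign(exposure)
    counts = np.bincount(q, minlength=6)[1:]
    if (counts == 0).any():
        raise ValueError("empty quintile after recoding")

    # quintile dummies with the chosen reference omitted
    n = len(y)
    qcols = [k for k in range(1, 6) if k != reference]
    Q = np.column_stack([(q == k).astype(float) for k in qcols])
    qnames = [f"quintile_{k}" for k in qcols]
    D_cov, cov_names = _dummies(covariates)
    D = np.hstack([Q, D_cov]) if D_cov.size else Q
    blocks = [np.ones((n, 1)), D]
    names = ["intercept"] + qnames + cov_names
    if centre_ids is not None:
        centre_levels = np.unique(centre_ids)
        E = (np.asarray(centre_ids)[:, None] == centre_levels[None, :]).astype(float)
    else:
        centre_levels = np.array([])
        E = np.empty((n, 0))
    X = np.hstack(blocks + ([E] if E.size else []))
    n_fixed = 1 + D.shape[1]
    sl_c = slice(n_fixed, X.shape[1])

    def run(s2):
        P = np.zeros((X.shape[1], X.shape[1]))
        if E.size:
            P[sl_c, sl_c] = np.eye(E.shape[1]) / max(s2, 1e-300)
        beta, H, loglik, _, _ = _pirls(X, y, P)
        V = np.linalg.inv(H + P)
        if E.size:
            sign, logdet_Hp = np.linalg.slogdet(H + P)
            laml = -(loglik - 0.5 * beta @ P @ beta) + 0.5 * logdet_Hp - 0.5 * (
                E.shape[1] * math.log(1.0 / max(s2, 1e-300))
            ) - 0.5 * E.shape[1] * math.log(2 * math.pi)
        else:
            laml = -loglik
        return beta, V, laml

    if sigma2_u is None and E.size:
        best = None
        for s2 in (0.001, 0.01, 0.05, 0.15, 0.4):
            beta, V, laml = run(s2)
            if best is None or laml < best[0]:
                best = (laml, s2, beta, V)
        _, sigma2_u, beta, V = best
    else:
        sigma2_u = sigma2_u or 0.0
        beta, V, _ = run(sigma2_u)

    zcrit = norm.ppf(1 - alpha / 2)
    rows = [{"quintile": reference, "or": 1.0, "lo": 1.0, "hi": 1.0, "log_or": 0.0, "se": 0.0}]
    for k in range(1, 6):
        if k == reference:
            continue
        col = f"quintile_{k}"
        j = names.index(col)
        b, se = beta[j], math.sqrt(V[j, j])
        rows.append(
            {
                "quintile": k,
                "or": math.exp(b),
                "lo": math.exp(b - zcrit * se),
                "hi": math.exp(b + zcrit * se),
                "log_or": b,
                "se": se,
            }
        )
    table = pd.DataFrame(rows).sort_values("quintile").reset_index(drop=True)
    return QuintileFit(cutpoints=cuts, reference=reference, table=table, sigma2_u=float(sigma2_u))
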