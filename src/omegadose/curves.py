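"""Adjusted-prevalence curve extraction and landmark analysis.

The fitted model is summarised as a curve of adjusted outcome prevalence
against intake over the 0.25th-99.75th percentile range, with a +/- 1 SEM
band.  "Adjusted prevalence" is computed by standardisation over the
analytic sample: the linear predictor at grid intake ``x`` is averaged
over the observed covariate and centre distribution and mapped through the
inverse logit (an alternative that averages on the probability scale is
available via ``scale="response"``).  The SEM is obtained by the delta
method on the logit scale and mapped through the inverse logit, so the
band is asymmetric and always inside (0, 1).

Landmarks mirror the headline quantities of this kind of analysis: the
starting prevalence at the left edge of the range, the curve minimum with
its intake location and empirical percentile, and locations where a band
limit crosses a reference prevalence level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .gamm import DoseResponseFit

__all__ = [
    "CurveSummary",
    "CurveLandmarks",
    "adjusted_prevalence_curve",
    "pooled_prevalence_curve",
    "find_minimum",
    "band_crossing",
    "percentile_of",
    "extract_landmarks",
]


@dataclass
class CurveLandmarks:
    start_value: float
    min_value: float
    min_location: float
    min_percentile: float
    crossings: list[dict] = field(default_factory=list)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "start_value": float(self.start_value),
                    "min_value": float(self.min_value),
                    "min_location": float(self.min_location),
                    "min_percentile": float(self.min_percentile),
                    "crossings": self.crossings,
                },
                fh,
                sort_keys=False,
            )


@dataclass
class CurveSummary:
    """Grid of intake vs adjusted prevalence with a +/- 1 SEM band."""

    grid: pd.DataFrame  # intake, percentile, prevalence, sem_lower, sem_upper
    landmarks: CurveLandmarks | None = None

    def __post_init__(self) -> None:
        g = self.grid
        req = {"intake", "prevalence", "sem_lower", "sem_upper"}
        if not req.issubset(g.columns):
            raise ValueError(f"curve grid needs columns {sorted(req)}")
        if not g["intake"].is_monotonic_increasing or g["intake"].duplicated().any():
            raise ValueError("intake grid must be strictly increasing")
        vals = g[["prevalence", "sem_lower", "sem_upper"]].to_numpy()
        if (vals <= 0).any() or (vals >= 1).any():
            raise ValueError("prevalences and band limits must lie in (0, 1)")
        if (g["sem_lower"] > g["prevalence"]).any() or (g["prevalence"] > g["sem_upper"]).any():
            raise ValueError("band must bracket the prevalence curve")

    def to_csv(self, path) -> None:
        self.grid.to_csv(path, index=False)

    def plot(self, ax=None, **kwargs):
        """Basic line plot with the +/- SEM band as dashed envelopes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self.grid
        ax.plot(g["intake"], 100 * g["prevalence"], color="black", **kwargs)
        ax.plot(g["intake"], 100 * g["sem_lower"], color="black", ls="--", lw=0.8)
        ax.plot(g["intake"], 100 * g["sem_upper"], color="black", ls="--", lw=0.8)
        ax.set_xlabel("energy-adjusted omega-3 intake (g/day)")
        ax.set_ylabel("adjusted prevalence (%)")
        return ax


def percentile_of(intakes, x) -> float:
    """Empirical percentile of ``x`` in the intake sample (mid-rank ECDF).

    Defined as 100 * (#{X < x} + 0.5 #{X = x}) / n, so a value below every
    observation maps to 0 and the sample median to ~50.
    """
    arr = np.asarray(pd.Series(intakes).dropna(), dtype=float)
    if arr.size == 0:
        raise ValueError("empty intake sample")
    below = np.count_nonzero(arr < x)
    equal = np.count_nonzero(arr == x)
    return 100.0 * (below + 0.5 * equal) / arr.size


#: linear predictors are clamped here before the inverse logit so that
#: curve values and band limits stay inside the open interval (0, 1) in
#: floating point; a band that sits at the clamp accompanies a fit whose
#: ``separation`` flag is set and should not be interpreted.
_ETA_CURVE_CLIP = 36.0


def _expit_open(eta):
    return expit(np.clip(eta, -_ETA_CURVE_CLIP, _ETA_CURVE_CLIP))


def _eta_bar_and_se(fit: DoseResponseFit, log_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rows = np.stack([fit.mean_design_row(z) for z in log_grid])
    eta = rows @ fit.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", rows, fit.cov, rows))
    return eta, se


def adjusted_prevalence_curve(
    fit: DoseResponseFit,
    intakes,
    grid_size: int = 200,
    percentile_range: tuple[float, float] = (0.25, 99.75),
    scale: str = "logit",
    log_constant: float = 0.005,
) -> CurveSummary:
    """Standardised prevalence +/- 1 SEM over the intake percentile range.

    The grid is equally spaced on the shifted-log intake scale,
    ``log(x + log_constant)``, between the two percentile endpoints of the
    observed (energy-adjusted) intakes; ``log_constant`` must match the
    transform the model was fitted on.  With ``scale="logit"`` (default)
    the linear predictor is averaged over the sample before applying the
    inverse logit; ``scale="response"`` averages fitted probabilities
    instead (the band keeps the logit-scale delta-method width in both
    cases).
    """
    if scale not in {"logit", "response"}:
        raise ValueError("scale must be 'logit' or 'response'")
    if log_constant <= 0:
        raise ValueError("log_constant must be positive")
    lo_p, hi_p = percentile_range
    if not 0 <= lo_p < hi_p <= 100:
        raise ValueError("invalid percentile range")
    arr = np.asarray(pd.Series(intakes).dropna(), dtype=float)
    lo, hi = np.percentile(arr, [lo_p, hi_p])
    b_lo, b_hi = fit.basis.range
    if math.log(lo + log_constant) < b_lo - 1e-9 or math.log(hi + log_constant) > b_hi + 1e-9:
        raise ValueError("requested grid extends outside the fitted data range")
    log_grid = np.linspace(math.log(lo + log_constant), math.log(hi + log_constant), grid_size)
    grid = np.exp(log_grid) - log_constant

    eta_bar, se = _eta_bar_and_se(fit, log_grid)
    if scale == "logit":
        prev = _expit_open(eta_bar)
        lower = _expit_open(eta_bar - se)
        upper = _expit_open(eta_bar + se)
    else:
        # average fitted probabilities over the sample at each grid point
        s_vals = fit.spline_values(log_grid)
        prev = np.array([np.mean(expit(fit.row_offsets + s)) for s in s_vals])
        # keep the logit-scale delta-method band width, recentred on the
        # response-scale point estimate
        lower = _expit_open(logit(prev) - se)
        upper = _expit_open(logit(prev) + se)

    frame = pd.DataFrame(
        {
            "intake": grid,
            "percentile": [percentile_of(arr, x) for x in grid],
            "prevalence": prev,
            "sem_lower": lower,
            "sem_upper": upper,
        }
    )
    summary = CurveSummary(grid=frame)
    summary.landmarks = extract_landmarks(summary)
    return summary


def pooled_prevalence_curve(curves: list[CurveSummary]) -> CurveSummary:
    """Rubin-rule pooling of curves from multiply imputed fits, pointwise.

    Pooling happens on the logit scale: points are averaged and the band
    width uses total variance W + (1 + 1/m) B at each grid point.
    """
    if len(curves) < 1:
        raise ValueError("need at least one curve")
    if len(curves) == 1:
        return curves[0]
    m = len(curves)
    base = curves[0].grid
    etas = np.stack([logit(c.grid["prevalence"].to_numpy()) for c in curves])
    ses = np.stack(
        [logit(c.grid["sem_upper"].to_numpy()) - logit(c.grid["prevalence"].to_numpy()) for c in curves]
    )
    point = etas.mean(axis=0)
    W = (ses**2).mean(axis=0)
    B = etas.var(axis=0, ddof=1)
    T = W + (1 + 1 / m) * B
    se = np.sqrt(T)
    frame = pd.DataFrame(
        {
            "intake": base["intake"].to_numpy(),
            "percentile": base["percentile"].to_numpy(),
            "prevalence": _expit_open(point),
            "sem_lower": _expit_open(point - se),
            "sem_upper": _expit_open(point + se),
        }
    )
    summary = CurveSummary(grid=frame)
    summary.landmarks = extract_landmarks(summary)
    return summary


def find_minimum(curve: CurveSummary) -> tuple[float, float]:
    """Global minimum of the prevalence curve: (min_value, min_location).

    Ties are broken toward smaller intake.
    """
    g = curve.grid
    i = int(np.argmin(g["prevalence"].to_numpy()))  # argmin returns first minimum
    return float(g["prevalence"].iloc[i]), float(g["intake"].iloc[i])


def band_crossing(
    curve: CurveSummary,
    side: str,
    reference: float,
    from_location: float | None = None,
) -> float | None:
    """Smallest intake >= from_location where a band limit crosses ``reference``.

    A crossing means the chosen limit passes the reference level between
    two adjacent grid points (either direction); the location is linearly
    interpolated.  Returns None if the limit never crosses.
    """
    if side not in {"upper", "lower"}:
        raise ValueError("side must be 'upper' or 'lower'")
    if not 0.0 < reference < 1.0:
        raise ValueError("reference prevalence must lie in (0, 1)")
    g = curve.grid
    x = g["intake"].to_numpy()
    yv = g[f"sem_{side}"].to_numpy()
    start = x[0] if from_location is None else from_location
    diff = yv - reference
    for i in range(len(x) - 1):
        if x[i + 1] < start:
            continue
        a, b = diff[i], diff[i + 1]
        if a == 0.0 and x[i] >= start:
            return float(x[i])
        if a * b < 0:
            t = a / (a - b)
            loc = x[i] + t * (x[i + 1] - x[i])
            if loc >= start:
                return float(loc)
    if diff[-1] == 0.0:
        return float(x[-1])
    return None


def extract_landmarks(
    curve: CurveSummary, crossing_specs: list[dict] | None = None
) -> CurveLandmarks:
    """Start value, minimum (with percentile) and any requested band crossings.

    ``crossing_specs`` entries are dicts with keys ``side`` and
    ``reference`` (and optionally ``from_location``); by default one
    crossing is computed: where the upper band limit regains the initial
    lower band value after the minimum (the "flat from there onward"
    landmark of this analysis).
    """
    g = curve.grid
    min_value, min_location = find_minimum(curve)
    i_min = int(np.argmin(g["prevalence"].to_numpy()))
    min_pct = float(g["percentile"].iloc[i_min]) if "percentile" in g else float("nan")
    start_value = float(g["prevalence"].iloc[0])
    if crossing_specs is None:
        crossing_specs = [
            {
                "side": "upper",
                "reference": float(g["sem_lower"].iloc[0]),
                "from_location": min_location,
            }
        ]
    crossings = []
    for spec in crossing_specs:
        loc = band_crossing(
            curve, spec["side"], spec["reference"], spec.get("from_location")
        )
        entry = {
            "side": spec["side"],
            "reference": float(spec["reference"]),
            "location": None if loc is None else float(loc),
            "percentile": None,
        }
        if loc is not None and "percentile" in g:
            entry["percentile"] = float(np.interp(loc, g["intake"], g["percentile"]))
        crossings.append(entry)
    return CurveLandmarks(
        start_value=start_value,
        min_value=min_value,
        min_location=min_location,
        min_percentile=min_pct,
        crossings=crossings,
    )
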