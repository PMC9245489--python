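"""Residual-method energy adjustment on the log scale.

Absolute nutrient intake is strongly driven by total energy intake; the
residual method (Willett) removes that component.  Both nutrient and energy
are transformed with a constant-shifted log, ``log(x + c)`` with
``c = 0.005`` (half the smallest unit of measurement), so that zero intakes
remain in the domain.  The nutrient is regressed on energy by ordinary
least squares; each participant's residual is added to the predicted
log-nutrient at the *mean* log energy, the sum is exponentiated, and the
constant is subtracted (floored at zero) to return to g/day.

The adjusted variable is uncorrelated with log energy on the fitting sample
and preserves intake ranking among participants sharing an energy value.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

__all__ = ["DEFAULT_LOG_CONSTANT", "AdjustmentModel", "log_shift", "fit_adjustment", "adjust"]

#: Half the smallest unit of measurement of the intake variable.
DEFAULT_LOG_CONSTANT = 0.005


def log_shift(x, c: float = DEFAULT_LOG_CONSTANT):
    """Constant-shifted log transform ``log(x + c)`` for nonnegative ``x``."""
    if c <= 0:
        raise ValueError("shift constant c must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("log_shift requires nonnegative input")
    out = np.log(x + c)
    return float(out) if out.ndim == 0 else out


@dataclass
class AdjustmentModel:
    """Fitted log-log nutrient-on-energy regression used for adjustment."""

    constant_c: float
    slope: float
    intercept: float
    mean_log_energy: float
    fitted_on_n: int

    def predicted_at_mean(self) -> float:
        """Predicted log nutrient at the mean log energy of the fitting sample."""
        return self.intercept + self.slope * self.mean_log_energy

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AdjustmentModel":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def fit_adjustment(
    intakes, energies, c: float = DEFAULT_LOG_CONSTANT
) -> AdjustmentModel:
    """OLS of log(intake + c) on log(energy + c).

    Requires at least two observations and non-degenerate energy variation.
    """
    intakes = np.asarray(intakes, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if intakes.shape != energies.shape or intakes.ndim != 1:
        raise ValueError("intakes and energies must be 1-d arrays of equal length")
    if len(intakes) < 2:
        raise ValueError("need at least two observations to fit the adjustment")
    y = log_shift(intakes, c)
    x = log_shift(energies, c)
    if np.ptp(x) == 0 or np.var(x) < 1e-14:
        raise np.linalg.LinAlgError("zero variance in log energy: singular fit")
    slope, intercept = np.polyfit(x, y, 1)
    return AdjustmentModel(
        constant_c=c,
        slope=float(slope),
        intercept=float(intercept),
        mean_log_energy=float(np.mean(x)),
        fitted_on_n=len(intakes),
    )


def adjust(model: AdjustmentModel, intakes, energies):
    """Energy-adjusted intake: exp(residual + prediction-at-mean-energy) - c, floored at 0."""
    intakes = np.asarray(intakes, dtype=float)
    energies = np.asarray(energies, dtype=float)
    c = model.constant_c
    y = log_shift(intakes, c)
    x = log_shift(energies, c)
    residual = y - (model.intercept + model.slope * x)
    adjusted_log = residual + model.predicted_at_mean()
    out = np.maximum(np.exp(adjusted_log) - c, 0.0)
    return float(out) if out.ndim == 0 else out
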