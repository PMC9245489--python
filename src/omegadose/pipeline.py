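"""End-to-end pipeline: generate -> intake -> adjust -> impute -> fit -> summarise.

Orchestrates the full analysis as a reproducible run driven by a single
``RunConfig`` (YAML-serialisable) and seed: every stage writes its
intermediate artefact under the run directory, and the machine-readable
``report.yaml`` echoes the configuration so a run can be regenerated
byte-identically.  Also houses the cohort-accounting helpers
(``participant_flow``, ``prevalence``).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .cohort import Cohort, CohortConfig, binarise_outcome, generate_cohort, intake_percentiles
from .curves import adjusted_prevalence_curve, pooled_prevalence_curve
from .energy import adjust, fit_adjustment
from .ffq import CompositionTable, intakes_from_long
from .gamm import fit_gamm, fit_quintiles, select_smoothing
from .impute import ImputationSpec, mice, pool
from .sensitivity import design_terms_from_covariates, evalue_from_curve, gvif

__all__ = ["RunConfig", "run_pipeline", "participant_flow", "prevalence", "PipelineError"]

log = logging.getLogger("omegadose")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "run"
    n_pairs: int = 6000
    seed: int = 0
    outcomes: tuple[str, ...] = ("ipv_physical", "ipv_emotional")
    m: int = 10
    mi_iterations: int = 10
    quintile_reference: dict[str, int] = field(
        default_factory=lambda: {"ipv_physical": 3, "ipv_emotional": 4}
    )
    smoothing_criterion: str = "reml"
    n_basis: int = 10
    grid_size: int = 200
    percentile_range: tuple[float, float] = (0.25, 99.75)
    curve_scale: str = "logit"
    cohort_dir: str | None = None  # load instead of generate when set

    def __post_init__(self) -> None:
        lo, hi = self.percentile_range
        if not (0 < lo < hi < 100):
            raise ValueError("percentile range must satisfy 0 < low < high < 100")
        for out, ref in self.quintile_reference.items():
            if ref not in range(1, 6):
                raise ValueError(f"quintile reference for {out!r} must be in 1..5")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["percentile_range"] = list(self.percentile_range)
        d["outcomes"] = list(self.outcomes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["percentile_range"] = tuple(d.get("percentile_range", (0.25, 99.75)))
        d["outcomes"] = tuple(d.get("outcomes", ("ipv_physical", "ipv_emotional")))
        return cls(**d)


def participant_flow(starting_n: int, exclusions: list[tuple[str, int]]) -> dict:
    """Sequential exclusion cascade with a per-step audit ledger."""
    if starting_n < 0:
        raise ValueError("starting count must be nonnegative")
    running = starting_n
    ledger = []
    for label, count in exclusions:
        if count < 0:
            raise ValueError(f"negative exclusion count for {label!r}")
        if count > running:
            raise ValueError(
                f"exclusion {label!r} ({count}) exceeds running total ({running})"
            )
        running -= count
        ledger.append({"step": label, "excluded": count, "remaining": running})
    return {"starting_n": starting_n, "steps": ledger, "analytic_n": running}


def prevalence(numerator: int, denominator: int) -> float:
    """Percentage 100*numerator/denominator, half-up rounded to 2 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# timings go to the log only so report.yaml is byte-identically
# regenerable from (config, seed)
def _stage(report, name, t0):
    dt = time.time() - t0
    log.info("stage %-12s %.2fs", name, dt)
    return time.time()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report dict (also written as YAML)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # out_dir is a location, not an analysis parameter: leaving it out keeps
    # report.yaml byte-identical when the same run lands elsewhere on disk
    echoed = dataclasses.asdict(config)
    echoed.pop("out_dir")
    report: dict = {
        "version": _pkg_version,
        "seed": config.seed,
        "config": yaml.safe_load(yaml.safe_dump(echoed)),
    }
    t0 = time.time()
    table = CompositionTable.default()

    # --- generate / load -------------------------------------------------
    try:
        if config.cohort_dir:
            cohort = Cohort.load(config.cohort_dir)
        else:
            cohort = generate_cohort(
                CohortConfig(n_pairs=config.n_pairs, seed=config.seed), table
            )
        cohort.save(out / "cohort")
    except Exception as err:
        raise PipelineError("generate", str(err)) from err
    t0 = _stage(report, "generate", t0)

    # --- intake ----------------------------------------------------------
    try:
        intakes = intakes_from_long(cohort.ffq_long, table)
        intakes = intakes.reindex(cohort.pairs["pair_id"], fill_value=0.0)
        pairs = cohort.pairs.copy()
        pairs["omega3_g_day"] = intakes["omega3_g_day"].to_numpy()
        pairs["energy_kcal_day"] = intakes["energy_kcal_day"].to_numpy()
        intakes.to_csv(out / "intake.csv")
    except Exception as err:
        raise PipelineError("intake", str(err)) from err
    t0 = _stage(report, "intake", t0)

    # --- energy adjustment ----------------------------------------------
    try:
        model = fit_adjustment(
            pairs["omega3_g_day"].to_numpy(), pairs["energy_kcal_day"].to_numpy()
        )
        pairs["omega3_adj_g_day"] = adjust(
            model, pairs["omega3_g_day"].to_numpy(), pairs["energy_kcal_day"].to_numpy()
        )
        model.to_yaml(out / "adjustment.yaml")
        pairs.to_csv(out / "cohort_adjusted.csv", index=False)
        pct = intake_percentiles(pairs["omega3_adj_g_day"])
        report["intake_percentiles_g_day"] = {k: round(float(v), 3) for k, v in pct.items()}
    except Exception as err:
        raise PipelineError("adjust", str(err)) from err
    t0 = _stage(report, "adjust", t0)

    # --- multiple imputation ---------------------------------------------
    try:
        schema = cohort.schema()
        spec = ImputationSpec(m=config.m, n_iterations=config.mi_iterations, seed=config.seed)
        completed = mice(pairs, schema, spec)
        imp_dir = out / "imputed"
        imp_dir.mkdir(exist_ok=True)
        for k, df in enumerate(completed, 1):
            df.to_csv(imp_dir / f"imp_{k}.csv", index=False)
    except Exception as err:
        raise PipelineError("impute", str(err)) from err
    t0 = _stage(report, "impute", t0)

    covariate_names = [
        n for n, s in schema.items() if s["kind"] in ("categorical", "ordinal") and not n.endswith("_likert")
    ]
    report["outcomes"] = {}

    for outcome in config.outcomes:
        col = f"{outcome}_likert"
        entry: dict = {}
        # --- fit + curve per imputed dataset, pooled ---------------------
        try:
            curves = []
            any_separation = False
            sel_lam = sel_s2 = None
            quint_logor: dict[int, list[tuple[float, float]]] = {}
            ref = config.quintile_reference.get(outcome, 1)
            for k, df in enumerate(completed):
                y = binarise_outcome(df[col]).to_numpy(float)
                z = np.log(df["omega3_adj_g_day"].to_numpy() + model.constant_c)
                cov = df[covariate_names]
                centres = df["centre_id"].to_numpy()
                if k == 0:
                    fit, _trace = select_smoothing(
                        z, y, cov, centres,
                        n_basis=config.n_basis, criterion=config.smoothing_criterion,
                    )
                    sel_lam, sel_s2 = fit.lam, fit.sigma2_u
                    fit.save(out / f"fit_{outcome}")
                else:
                    fit = fit_gamm(z, y, cov, centres, sel_lam, sel_s2, n_basis=config.n_basis)
                if fit.separation:
                    any_separation = True
                    log.warning("possible separation in %s fit (imputation %d)", outcome, k + 1)
                curves.append(
                    adjusted_prevalence_curve(
                        fit,
                        df["omega3_adj_g_day"],
                        grid_size=config.grid_size,
                        percentile_range=config.percentile_range,
                        scale=config.curve_scale,
                    )
                )
                qf = fit_quintiles(
                    df["omega3_adj_g_day"].to_numpy(), y, cov, centres, reference=ref
                )
                for _, row in qf.table.iterrows():
                    if int(row["quintile"]) == ref:
                        continue
                    quint_logor.setdefault(int(row["quintile"]), []).append(
                        (row["log_or"], row["se"] ** 2)
                    )
            curve = pooled_prevalence_curve(curves)
            curve.to_csv(out / f"curve_{outcome}.csv")
            curve.landmarks.to_yaml(out / f"landmarks_{outcome}.yaml")
            try:
                ax = curve.plot()
                ax.figure.savefig(out / f"curve_{outcome}.png", dpi=100)
                import matplotlib.pyplot as plt

                plt.close(ax.figure)
            except Exception:  # plotting is best-effort (headless envs)
                pass
            lm = curve.landmarks
            entry["curve"] = {
                "start_prevalence_pct": round(100 * lm.start_value, 2),
                "min_prevalence_pct": round(100 * lm.min_value, 2),
                "min_intake_g_day": round(lm.min_location, 2),
                "min_percentile": round(lm.min_percentile, 1),
                "crossings": lm.crossings,
                "lam": float(sel_lam),
                "sigma2_u": float(sel_s2),
                "separation_flagged": bool(any_separation),
            }
        except Exception as err:
            raise PipelineError(f"fit:{outcome}", str(err)) from err
        t0 = _stage(report, f"fit:{outcome}", t0)

        # --- quintile sensitivity (Rubin-pooled on the log-odds scale) ---
        try:
            qrows = [{"quintile": ref, "or": 1.0, "lo": 1.0, "hi": 1.0}]
            for qk in sorted(quint_logor):
                ests, vars_ = zip(*quint_logor[qk])
                p = pool(np.asarray(ests), np.asarray(vars_))
                lo, hi = p.ci()
                qrows.append(
                    {
                        "quintile": qk,
                        "or": round(float(np.exp(p.point)), 3),
                        "lo": round(float(np.exp(lo)), 3),
                        "hi": round(float(np.exp(hi)), 3),
                    }
                )
            entry["quintiles"] = {"reference": ref, "odds_ratios": sorted(qrows, key=lambda r: r["quintile"])}
        except Exception as err:
            raise PipelineError(f"quintiles:{outcome}", str(err)) from err

        # --- E-value ------------------------------------------------------
        ev = evalue_from_curve(curve)
        entry["evalue"] = {"rr": round(ev.rr, 2), "evalue": round(ev.evalue, 2), "source": ev.source}
        report["outcomes"][outcome] = entry
        t0 = _stage(report, f"sensitivity:{outcome}", t0)

    # --- multicollinearity (GVIF on first completed dataset) -------------
    try:
        design, terms = design_terms_from_covariates(completed[0][covariate_names])
        g = gvif(design, terms)
        report["gvif"] = {
            t: {"gvif": round(float(r["gvif"]), 3), "gvif_scaled": round(float(r["gvif_scaled"]), 3)}
            for t, r in g.iterrows()
        }
        g.to_csv(out / "gvif.csv")
    except Exception as err:
        raise PipelineError("gvif", str(err)) from err
    t0 = _stage(report, "gvif", t0)

    report["pooled_over_imputations"] = config.m
    with open(out / "report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)
    return report
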