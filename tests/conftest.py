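import numpy as np
import pandas as pd
import pytest

from omegadose.cohort import CohortConfig, GroundTruthCurve, OutcomeSpec, generate_cohort
from omegadose.ffq import CompositionTable

NON_COVARIATE = ("pair_id", "centre_id", "omega3_g_day", "energy_kcal_day")


def covariate_columns(pairs: pd.DataFrame) -> list[str]:
    return [
        c for c in pairs.columns if c not in NON_COVARIATE and not c.endswith("_likert")
    ]


@pytest.fixture(scope="session")
def comp_table() -> CompositionTable:
    return CompositionTable.default()


@pytest.fixture(scope="session")
def small_cohort():
    """A complete (no missingness) 6000-pair cohort shared across tests."""
    cfg = CohortConfig(n_pairs=6000, seed=7, missingness_rates={})
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def flat_cohort():
    """Cohort with no exposure effect, no covariate effects, no clustering."""
    cfg = CohortConfig(
        n_pairs=20000,
        seed=11,
        centre_sd=0.0,
        covariate_effects={},
        missingness_rates={},
        outcomes={"y": OutcomeSpec(0.1246, GroundTruthCurve("flat"))},
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
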