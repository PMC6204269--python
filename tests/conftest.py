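import numpy as np
import pandas as pd
import pytest

from lesionsem.cohort import SubjectTable, generate_cohort
from lesionsem.study import interaction_cohort_config, moderation_base_spec


@pytest.fixture(scope="session")
def interaction_cohort():
    """One moderate-size cohort with a known lesion x connectivity
    interaction (omega_ef = 0.8) shared across tests."""
    return generate_cohort(interaction_cohort_config(n_total=1000, omega_ef=0.8, seed=42))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort generated without any interaction (omega_ef = 0)."""
    return generate_cohort(interaction_cohort_config(n_total=1000, omega_ef=0.0, seed=43))


@pytest.fixture(scope="session")
def base_spec():
    return moderation_base_spec()


@pytest.fixture()
def tiny_table():
    """Deterministic 10-row table for arithmetic oracles."""
    rng = np.random.default_rng(7)
    df = pd.DataFrame({
        "group": ["HO"] * 5 + ["MCI"] * 5,
        "tmt_b": np.round(60 + 30 * rng.random(10), 1),
        "memory_score": np.round(rng.normal(size=10), 3),
    })
    return SubjectTable(df)
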