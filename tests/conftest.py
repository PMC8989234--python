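"""Shared fixtures: one default simulated cohort per test session."""

import numpy as np
import pandas as pd
import pytest

from crcpear.config import GeneratorConfig
from crcpear.simulate import add_carrier_column, simulate_cohort

SESSION_SEED = 20220407


@pytest.fixture(scope="session")
def sim():
    return simulate_cohort(GeneratorConfig(seed=SESSION_SEED))


@pytest.fixture(scope="session")
def cohort(sim):
    return add_carrier_column(sim.cohort_table)


@pytest.fixture()
def tiny_survival():
    """Four subjects, no ties: the partial likelihood is tractable by hand."""
    return pd.DataFrame({
        "id": [1, 2, 3, 4],
        "pedigree_id": [1, 2, 3, 4],
        "time_y": [1.0, 2.0, 3.0, 4.0],
        "event": [1, 1, 1, 0],
        "x": [1.0, 0.0, 1.0, 0.0],
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
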