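import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from fuzzylvef import CohortTable, default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def default_spec():
    return default_cohort_spec()


@pytest.fixture(scope="session")
def cohort936(default_spec):
    """One study-sized synthetic cohort, shared across tests."""
    return generate_cohort(default_spec, seed=7)


@pytest.fixture()
def small_table():
    """Tiny hand-built cohort table with a clean class signal in one column."""
    rng = np.random.default_rng(42)
    n = 60
    y = np.r_[np.ones(20, dtype=int), np.zeros(40, dtype=int)]
    signal = np.where(y == 1, 2.0, 0.0) + rng.standard_normal(n) * 0.5
    noise = rng.standard_normal(n)
    frame = pd.DataFrame(
        {"signal": signal, "noise": noise},
        index=pd.RangeIndex(n, name="patient_id"),
    )
    return CohortTable(data=frame, labels=pd.Series(y, index=frame.index))
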