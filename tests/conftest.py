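import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from acticohort import EpochSeries

MONDAY = "2022-03-07"  # midnight of a Monday


def make_series(
    axis1,
    axis2=None,
    axis3=None,
    steps=None,
    wear=None,
    start=MONDAY,
    epoch_length=60,
    subject_id="S01",
    placement="waist",
    visit="baseline",
) -> EpochSeries:
    axis1 = np.asarray(axis1)
    zeros = np.zeros(axis1.shape, dtype=np.int64)
    return EpochSeries(
        subject_id=subject_id,
        placement=placement,
        visit=visit,
        start_time=pd.Timestamp(start),
        axis1=axis1,
        axis2=zeros if axis2 is None else np.asarray(axis2),
        axis3=zeros if axis3 is None else np.asarray(axis3),
        steps=zeros if steps is None else np.asarray(steps),
        epoch_length=epoch_length,
        wear=wear,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete simulated cohort, shared across tests."""
    from acticohort import CohortConfig, simulate_cohort

    return simulate_cohort(CohortConfig(n_frda=6, n_ctr=4, days=7, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
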