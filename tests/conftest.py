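import numpy as np
import pytest

from prscore.synthetic_cohort import SimulationConfig, simulate_cohort
from prscore.io import bundle_from_cohort, run_pipeline


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-patient synthetic cohort shared by integration tests."""
    return simulate_cohort(SimulationConfig(n_patients=150, seed=20240301))


@pytest.fixture(scope="session")
def small_report(small_cohort):
    return run_pipeline(bundle_from_cohort(small_cohort))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
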