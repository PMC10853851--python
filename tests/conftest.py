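import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A 5-participant simulated study, reused across tests."""
    from puretone import CohortConfig, generate_cohort, run_study

    rng = np.random.default_rng(777)
    cohort = generate_cohort(CohortConfig(n_participants=5), rng=rng)
    return run_study(cohort, rng=rng)


@pytest.fixture(scope="session")
def full_study():
    """The default 30-participant study at the documented conditions."""
    from puretone import CohortConfig, generate_cohort, run_study

    rng = np.random.default_rng(20240125)
    cohort = generate_cohort(CohortConfig(), rng=rng)
    return run_study(cohort, rng=rng)
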