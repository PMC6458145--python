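import numpy as np
import pytest

from difekit.cohort import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient synthetic cohort shared by read-only tests."""
    return generate_cohort(SyntheticCohortConfig(n=300, seed=123, label="small"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
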