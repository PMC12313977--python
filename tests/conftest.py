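import numpy as np
import pytest

from ddmediate.simulate import SimulationConfig, simulate_cohort
from ddmediate.task import generate_trial_set


@pytest.fixture(scope="session")
def trial_set():
    return generate_trial_set()


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default cohort (155 subjects), shared across tests."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
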