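import numpy as np
import pytest

from chicnet.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-conditions synthetic study shared across read-only tests."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
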