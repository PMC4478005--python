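import numpy as np
import pytest

from otomorph import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-config synthetic dataset shared across tests."""
    return generate_dataset(SimConfig(rng_seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
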