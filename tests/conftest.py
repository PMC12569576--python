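import numpy as np
import pytest

from precursorpred import generate_dataset


@pytest.fixture(scope="session")
def clean_dataset():
    """Seeded noise-free planted-substructure dataset shared across tests."""
    return generate_dataset(120, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
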