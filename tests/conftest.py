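import numpy as np
import pytest

from succsite.simulate import SyntheticSpec, generate_dataset, encode_synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signal dataset shared across unit tests."""
    return generate_dataset(SyntheticSpec(n_positive=60, n_negative=60, seed=7))


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Encoded feature matrix of the shared dataset (label column last)."""
    return encode_synthetic(small_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
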