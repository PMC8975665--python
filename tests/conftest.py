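import numpy as np
import pytest

from hosmlp import make_synthetic, prepare


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fixture_dataset():
    """The standard well-separated synthetic table: 300 x 4, 2 classes."""
    return make_synthetic(
        n_samples=300, n_features=4, n_classes=2, separation=6.0, label_noise=0.0, seed=7
    )


@pytest.fixture(scope="session")
def fixture_split(fixture_dataset):
    split, record = prepare(fixture_dataset, rng=7)
    return split
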