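import numpy as np
import pytest

from helpers import make_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """J = K = 4, ~40 individuals; small enough for dense-matrix oracles."""
    ds, cond, params = make_dataset(groups=4, size=10.0, seed=7)
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
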