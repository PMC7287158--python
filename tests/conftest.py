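import numpy as np
import pytest

from mvpakit import synth


@pytest.fixture
def gaussian_pair():
    """Well-separated two-class Gaussian data (train, test split)."""
    ds, y = synth.gen_gaussian_classes(
        n_per_class=40, p=5, separation=2.5, seed=11
    )
    X = ds.values
    return X[:60], y[:60], X[60:], y[60:]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
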