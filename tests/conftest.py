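import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_two_class_data(rng, n_per_class=30, p=8, shift=2.0):
    """Well-separated two-class Gaussian toy data (p < n)."""
    X1 = rng.standard_normal((n_per_class, p)) + shift
    X2 = rng.standard_normal((n_per_class, p))
    X = np.vstack([X1, X2])
    y = np.repeat([1, 2], n_per_class)
    return X, y


@pytest.fixture
def toy_two_class(rng):
    return make_two_class_data(rng)
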