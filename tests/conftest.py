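import numpy as np
import pytest

from discut import ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_dataset(values, n1=None, labels=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if labels is None:
        n1 = n // 2 if n1 is None else n1
        labels = np.array(["g1"] * n1 + ["g2"] * (n - n1))
    return ExpressionDataset(values=values, labels=labels)


@pytest.fixture
def count_dataset(rng):
    """60 NB genes, 6 vs 6, no signal."""
    y = rng.negative_binomial(5, 0.05, size=(60, 12))
    return make_dataset(y)


@pytest.fixture
def gaussian_dataset(rng):
    y = rng.normal(10.0, 2.0, size=(50, 10))
    return make_dataset(y)
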