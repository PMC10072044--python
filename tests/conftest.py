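import numpy as np
import pytest

from efbdba import BDBAConfig, ExpressionDataset


class ScriptedRng:
    """Minimal generator stand-in with scripted uniform / integer streams.

    Lets operator tests force specific rand values (e.g. rand = 0.5) and
    trace updates by hand.
    """

    def __init__(self, randoms=(), integers=()):
        self._r = list(randoms)
        self._i = list(integers)

    def random(self, size=None):
        if size is None:
            return self._r.pop(0)
        return np.array([self._r.pop(0) for _ in range(int(size))])

    def integers(self, *args, **kwargs):
        return self._i.pop(0)

    def uniform(self, low=0.0, high=1.0):
        return low + self._r.pop(0) * (high - low)

    def choice(self, a, size=None, replace=True):
        n = int(size or 1)
        out = [self._i.pop(0) for _ in range(n)]
        return np.array(out)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def scripted():
    return ScriptedRng


@pytest.fixture
def small_config():
    return BDBAConfig(G=10, NP=6, rng_seed=0)


def make_dataset(values, labels, prefix="f"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionDataset(
        values=values,
        labels=np.asarray(labels, dtype=np.int8),
        feature_ids=[f"{prefix}{j}" for j in range(p)],
        sample_ids=[f"s{i}" for i in range(n)],
    )


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def separable_dataset():
    """Two wide-margin clusters: any SVM separates them perfectly."""
    rng = np.random.default_rng(7)
    n_per = 20
    a = rng.normal(-5.0, 0.3, size=(n_per, 4))
    b = rng.normal(5.0, 0.3, size=(n_per, 4))
    values = np.vstack([a, b])
    labels = np.array([0] * n_per + [1] * n_per)
    return make_dataset(values, labels)
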