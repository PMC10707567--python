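import numpy as np
import pytest

from maacnn.config import ModelConfig
from maacnn.synthetic import make_cohort, preset_spec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_cohort():
    """Strongly separable 3-view synthetic cohort (40+40 subjects)."""
    return make_cohort(preset_spec("separable", seed=7))


@pytest.fixture(scope="session")
def separable_views(separable_cohort):
    return separable_cohort.view_features()


@pytest.fixture(scope="session")
def test_config():
    return ModelConfig.test_scale(folds=5)


def numeric_gradient(fn, x, eps=1e-6):
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, dtype=np.float64)
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = fn(x)
        x[idx] = orig - eps
        fm = fn(x)
        x[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return grad
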