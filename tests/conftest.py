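import numpy as np
import pytest

from otashort import GPCMItem, GPCMModel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_item(rng, m: int | None = None, a_range=(0.2, 2.0)) -> GPCMItem:
    """A random GPCM item with ordered thresholds."""
    m = m or int(rng.integers(2, 7))
    a = float(rng.uniform(*a_range))
    b = np.sort(rng.normal(0.0, 1.0, size=m - 1))
    b += 1e-3 * np.arange(m - 1)
    return GPCMItem(a, b)


def small_model(rng, n_items=3, m=3) -> GPCMModel:
    return GPCMModel(items=[random_item(rng, m=m) for _ in range(n_items)])
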