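import numpy as np
import pytest

from manovasim import GroupedSample


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_sample(seed: int, sizes=(10, 10, 10), p: int = 2, shifts=None) -> GroupedSample:
    """Normal grouped sample; optional per-group mean shift on variable 0."""
    rng = np.random.default_rng(seed)
    blocks = []
    for i, n in enumerate(sizes):
        x = rng.normal(size=(n, p))
        if shifts is not None:
            x[:, 0] += shifts[i]
        blocks.append(x)
    return GroupedSample(tuple(blocks))


@pytest.fixture
def small_sample():
    return random_sample(42, sizes=(8, 10, 12), p=2)
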