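import numpy as np
import pytest

from amda import AbundanceTable, GroupLabels


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def small_counts(rng):
    """A 10 x 6 count table with some exact zeros."""
    counts = rng.poisson(20, size=(10, 6)).astype(float)
    counts[rng.random(counts.shape) < 0.15] = 0.0
    counts[0, 0] = 0.0  # guarantee at least one zero
    return AbundanceTable(counts)


@pytest.fixture
def small_labels():
    return GroupLabels(np.repeat([1, 2], 5))


@pytest.fixture
def random_clr(rng):
    """A 12 x 5 CLR matrix from random compositions."""
    from amda import clr, to_composition

    x = AbundanceTable(rng.gamma(2.0, size=(12, 5)))
    return clr(to_composition(x))
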