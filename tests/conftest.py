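import numpy as np
import pytest

from baystmix.graphs import lattice_adjacency, temporal_path_adjacency
from baystmix.model_core import CountData


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_lattice():
    return lattice_adjacency(3, 3)


@pytest.fixture
def path5():
    return temporal_path_adjacency(5)


@pytest.fixture
def tiny_counts(rng):
    """4 areas x 5 time points of Poisson counts around E with mu ~ 1."""
    E = rng.uniform(20.0, 60.0, size=(4, 5))
    Y = rng.poisson(E)
    return CountData(Y=Y, E=E)
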