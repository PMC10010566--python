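import numpy as np
import pytest

from persnet.graphcore import WeightedNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20230313)


@pytest.fixture
def fig1_network():
    """4-node toy graph with edges (a,b)=W2, (a,c)=W3, (a,d)=W1, (b,c)=W5,
    (b,d)=W4, (c,d)=W6 where W1 < W2 < ... < W6.

    Canonical edge order for p=4 is (0,1),(0,2),(0,3),(1,2),(1,3),(2,3).
    """
    w = {1: 0.10, 2: 0.25, 3: 0.40, 4: 0.55, 5: 0.70, 6: 0.85}
    weights = np.array([w[2], w[3], w[1], w[5], w[4], w[6]])
    return WeightedNetwork(4, weights), w


@pytest.fixture
def make_random_network(rng):
    def _make(p, distinct=True):
        q = p * (p - 1) // 2
        weights = rng.uniform(0, 1, q)
        return WeightedNetwork(p, weights)

    return _make
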