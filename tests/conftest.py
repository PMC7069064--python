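import numpy as np
import pytest

import lollinet as ln


@pytest.fixture
def p3():
    """Unit-weight 3-node path."""
    return ln.WeightedGraph(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float))


@pytest.fixture
def k5():
    return ln.make_complete(5)


@pytest.fixture
def fig1_toy():
    """Five-node toy: node a tied to c,d,e at 0.9; node b to the same at 0.1."""
    w = np.zeros((5, 5))
    for j in (2, 3, 4):
        w[0, j] = w[j, 0] = 0.9
        w[1, j] = w[j, 1] = 0.1
    return ln.WeightedGraph(w, list("abcde"))


@pytest.fixture
def small_lollipop():
    """12-node lollipop: 8-clique with a 4-node stick."""
    return ln.make_lollipop(12, 4)


def random_connected_weighted(n, seed, density=0.4):
    """Random connected graph with U(0,1) weights thresholded to density."""
    rng = np.random.default_rng(seed)
    for _ in range(200):
        w = rng.random((n, n))
        w = (w + w.T) / 2
        w[w < 1 - density] = 0.0
        np.fill_diagonal(w, 0.0)
        if ln.is_connected(w):
            return ln.WeightedGraph(w)
        seed += 1
        rng = np.random.default_rng(seed)
    raise RuntimeError("could not build a connected fixture graph")
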