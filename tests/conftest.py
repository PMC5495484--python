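import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chain_graph():
    """a -> b -> c, unit weights."""
    g = nx.DiGraph()
    g.add_edge("a", "b", weight=1.0)
    g.add_edge("b", "c", weight=1.0)
    return g


@pytest.fixture
def fork_graph():
    """a -> b and a -> c, equal weights."""
    g = nx.DiGraph()
    g.add_edge("a", "b", weight=1.0)
    g.add_edge("a", "c", weight=1.0)
    return g


def lagged_pair(n=41, lag=3, coupling=0.9, noise_sd=0.1, seed=0):
    """Regulator/target pair with y_t = coupling * x_{t-lag} + noise."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    y[lag:] = coupling * x[: n - lag]
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return x, y
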