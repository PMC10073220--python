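import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20230404)


def random_connected_graph(n, rng, p=0.35):
    """Small random simple graph, resampled until connected."""
    import networkx as nx

    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if n == 1 or nx.is_connected(g):
            return g
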