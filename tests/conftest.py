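import numpy as np
import pytest

import ctdpair as cp


@pytest.fixture
def path5():
    """Five-node path a-b-c-d-e with unit weights."""
    return cp.new_graph(
        [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0), ("d", "e", 1.0)]
    )


@pytest.fixture
def random_instance():
    """Factory for seeded (graph, module) instances on small random graphs."""

    def make(seed: int, n: int = 15, degree: float = 3.0, module_size: int = 4):
        rng = np.random.default_rng(seed)
        G = cp.random_connected_graph(n, degree, seed)
        labels = sorted(G.nodes)
        idx = sorted(rng.choice(len(labels), size=module_size, replace=False))
        S = cp.NodeModule(tuple(labels[i] for i in idx))
        return G, S

    return make
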