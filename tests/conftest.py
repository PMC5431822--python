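import numpy as np
import pytest

from multiplex_axelrod import CultureState, MultiplexNetwork, init_culture


def random_multiplex(rng, N=None, F=None, edge_prob=0.3) -> MultiplexNetwork:
    """Small random multiplex with at least one edge, for property tests."""
    N = N or int(rng.integers(4, 21))
    F = F or int(rng.integers(1, 5))
    while True:
        layers = []
        for _ in range(F):
            edges = [
                (a, b)
                for a in range(N)
                for b in range(a + 1, N)
                if rng.random() < edge_prob
            ]
            layers.append(edges)
        if any(layers):
            return MultiplexNetwork(range(N), layers)


def random_instance(rng, q=None):
    """Random (multiplex, culture state) pair on a small node set."""
    net = random_multiplex(rng)
    q = q or int(rng.integers(1, 5))
    state = init_culture(net.N, net.F, q, rng)
    return net, state


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def triangle_net():
    """One triangle layer plus one single-edge layer on 4 nodes."""
    return MultiplexNetwork(
        ["a", "b", "c", "d"],
        [[("a", "b"), ("b", "c"), ("a", "c")], [("c", "d")]],
        ["ops", "trust"],
    )


@pytest.fixture
def pair_net():
    """Two agents linked on layers 0 and 1 of 3 (the frozen-bond toy)."""
    return MultiplexNetwork(["i", "j"], [[("i", "j")], [("i", "j")], []],
                            ["sport", "politics", "religion"])
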