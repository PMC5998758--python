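import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from coexsim import GeneratorConfig, WeightedNetwork, random_network


@pytest.fixture
def four_gene_pair():
    """The small worked instance used throughout: two 3-node networks
    sharing two nodes and one edge."""
    n1 = WeightedNetwork("n1", {"a", "b", "c"}, {("a", "b"): 0.8, ("b", "c"): 0.6})
    n2 = WeightedNetwork("n2", {"a", "b", "d"}, {("a", "b"): 0.4, ("a", "d"): 0.9})
    return n1, n2


@pytest.fixture
def triangle():
    return WeightedNetwork(
        "k3", {"a", "b", "c"}, {("a", "b"): 0.5, ("b", "c"): 0.5, ("a", "c"): 0.5}
    )


@pytest.fixture
def path3():
    return WeightedNetwork("p3", {"a", "b", "c"}, {("a", "b"): 0.5, ("b", "c"): 0.5})


def make_random_network(seed, label=None, n_nodes=25, density=0.3):
    cfg = GeneratorConfig(n_nodes=n_nodes, edge_density=density, seed=seed)
    return random_network(cfg, label or f"net{seed}")


def random_small_graph(rng: np.random.Generator, max_nodes=6):
    """Random unweighted graph as (nodes, edge pair list), possibly with
    isolated nodes."""
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.15, 0.9))
    nodes = [f"v{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return nodes, edges
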