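import networkx as nx
import numpy as np
import pytest

from hypervn import GeneratorSpec, figure1_fixture, random_hypergraph

FIG1_TEXT = "1,2,3\n2,3,4,5,6,7\n5,6,7,8\n4,9,10,11\n"


@pytest.fixture
def fig1():
    """Canonical 11-node / 4-hyperedge worked example."""
    return figure1_fixture()


@pytest.fixture
def fig1_text():
    return FIG1_TEXT


def random_hypergraphs(count, max_n=40, max_m=15, seed=0):
    """Stream of small random hypergraphs with varied sizes."""
    rng = np.random.default_rng(seed)
    for k in range(count):
        n = int(rng.integers(5, max_n + 1))
        m = int(rng.integers(2, max_m + 1))
        yield random_hypergraph(GeneratorSpec(
            n=n, m=m, cardinality="poisson",
            param=float(rng.uniform(1.5, 5.0)), seed=int(rng.integers(2**31))))


def random_nx_graphs(count, max_n=30, seed=0):
    """Stream of Erdős–Rényi graphs (some sparse enough to be disconnected)."""
    rng = np.random.default_rng(seed)
    for _ in range(count):
        n = int(rng.integers(2, max_n + 1))
        p = float(rng.uniform(0.05, 0.8))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        yield g
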