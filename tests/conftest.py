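import numpy as np
import pytest

from netlinkpred import BipartiteNetwork, UnipartiteGraph
from netlinkpred.synthetic import SyntheticSpec, gen_benchmark


@pytest.fixture
def toy_net():
    """Three-edge toy: d1-t1, d1-t2, d2-t2 (targets in rows)."""
    return BipartiteNetwork(np.array([[1, 0], [1, 1]]), ["t1", "t2"], ["d1", "d2"])


@pytest.fixture
def two_block_net():
    """Perfect two-module network: d1-t1, d2-t2."""
    return BipartiteNetwork(np.eye(2, dtype=int), ["t1", "t2"], ["d1", "d2"])


@pytest.fixture
def path3():
    """Path graph a-b-c."""
    adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return UnipartiteGraph(adj, ["a", "b", "c"])


@pytest.fixture
def cycle4():
    """4-cycle a-b-c-d-a."""
    adj = np.array(
        [[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]], dtype=float
    )
    return UnipartiteGraph(adj, ["a", "b", "c", "d"])


@pytest.fixture(scope="session")
def planted_benchmark():
    """The documented planted-structure study conditions (seed 1)."""
    return gen_benchmark(SyntheticSpec(seed=1))


def random_unipartite(rng, n_max=30, p=0.25, weighted=False):
    """Erdos-Renyi undirected graph with labelled nodes."""
    n = int(rng.integers(3, n_max + 1))
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1).astype(float)
    if weighted:
        w = np.triu(rng.uniform(0.1, 5.0, (n, n)), 1)
        adj = adj * w
    adj = adj + adj.T
    return UnipartiteGraph(adj, [f"n{i:02d}" for i in range(n)], weighted=weighted)


def random_bipartite(rng, n_t_max=12, n_d_max=12, p=0.35):
    """Random bipartite network with at least one edge."""
    n_t = int(rng.integers(2, n_t_max + 1))
    n_d = int(rng.integers(2, n_d_max + 1))
    A = (rng.random((n_t, n_d)) < p).astype(np.int8)
    if A.sum() == 0:
        A[int(rng.integers(n_t)), int(rng.integers(n_d))] = 1
    return BipartiteNetwork(
        A, [f"t{i:02d}" for i in range(n_t)], [f"d{i:02d}" for i in range(n_d)]
    )
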