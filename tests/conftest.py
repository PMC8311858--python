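import numpy as np
import pytest

from connseg.nodes import default_node_table
from connseg.partition import ModularPartition
from connseg.synthetic_data import default_design, make_partition


@pytest.fixture(scope="session")
def node_table():
    return default_node_table()


@pytest.fixture(scope="session")
def partition76(node_table):
    return make_partition(76, 7, node_table)


@pytest.fixture(scope="session")
def design(node_table, partition76):
    return default_design()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def random_graph_and_partition(rng, n, n_modules, edge_prob=0.3):
    """Seeded Erdos-Renyi adjacency plus a random full partition."""
    adj = rng.random((n, n)) < edge_prob
    adj = np.triu(adj, k=1)
    adj = adj | adj.T
    assignment = rng.integers(0, n_modules, size=n)
    # ensure every module id occurs so ids are contiguous
    assignment[:n_modules] = np.arange(n_modules)
    return adj, ModularPartition(assignment)


def brute_force_pc(adj, partition):
    """Independent per-node loop evaluation of the participation coefficient."""
    n = adj.shape[0]
    pc = np.zeros(n)
    for i in range(n):
        neighbors = [j for j in range(n) if adj[i, j]]
        k = len(neighbors)
        if k == 0:
            continue
        acc = 0.0
        for m in range(partition.n_modules):
            k_m = sum(1 for j in neighbors if partition.module_of(j) == m)
            acc += (k_m / k) ** 2
        pc[i] = 1.0 - acc
    return pc
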