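"""Participation coefficient and connection counts against brute-force oracles."""

import networkx as nx
import numpy as np
import pytest

from conftest import brute_force_pc, random_graph_and_partition
from connseg.graph_build import multi_threshold_graphs
from connseg.node_metrics import (
    hemisphere_connection_counts,
    module_connection_counts,
    participation_coefficient,
    threshold_averaged_pc,
    within_between_counts,
)
from connseg.partition import ModularPartition


def _star_adjacency(n, center, leaves):
    adj = np.zeros((n, n), dtype=bool)
    for leaf in leaves:
        adj[center, leaf] = adj[leaf, center] = True
    return adj


class TestParticipationCoefficient:
    def test_all_edges_within_own_module_gives_zero(self):
        # node 0 with 10 edges, all into its own module
        adj = _star_adjacency(12, 0, range(1, 11))
        part = ModularPartition(np.r_[np.zeros(11, int), 1])
        assert participation_coefficient(adj, part)[0] == 0.0

    def test_even_split_over_seven_modules(self):
        # one edge into each of 7 modules -> PC = 1 - 7*(1/7)^2 = 6/7
        adj = _star_adjacency(8, 0, range(1, 8))
        part = ModularPartition(np.r_[0, np.arange(7)])
        assert participation_coefficient(adj, part)[0] == pytest.approx(6 / 7)

    def test_isolated_node_gets_zero(self):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        part = ModularPartition(np.array([0, 1, 0, 1]))
        pc = participation_coefficient(adj, part)
        assert pc[2] == 0.0 and pc[3] == 0.0

    def test_matches_brute_force_on_random_graph(self, rng):
        adj, part = random_graph_and_partition(rng, 20, 3)
        assert np.allclose(
            participation_coefficient(adj, part), brute_force_pc(adj, part),
            atol=1e-13,
        )

    def test_networkx_input_agrees_with_adjacency(self, rng):
        adj, part = random_graph_and_partition(rng, 15, 4)
        g = nx.from_numpy_array(adj.astype(int))
        assert np.allclose(
            participation_coefficient(g, part),
            participation_coefficient(adj, part),
        )

    def test_graph_node_outside_partition_errors(self):
        g = nx.path_graph(5)
        part = ModularPartition(np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError, match="absent"):
            participation_coefficient(g, part)

    def test_bounded_by_one_minus_inverse_m(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            m = int(rng.integers(2, 7))
            adj, part = random_graph_and_partition(rng, n, m)
            pc = participation_coefficient(adj, part)
            assert np.all(pc >= 0.0)
            assert np.all(pc <= 1 - 1 / part.n_modules + 1e-12)

    def test_merging_modules_never_increases_pc(self, rng):
        """Coarsening property: merging two modules can only concentrate
        a node's connections."""
        for _ in range(10):
            adj, part = random_graph_and_partition(rng, 18, 4)
            merged = part.assignment.copy()
            merged[merged == 3] = 2
            coarser = ModularPartition(merged)
            assert np.all(
                participation_coefficient(adj, coarser)
                <= participation_coefficient(adj, part) + 1e-12
            )


class TestThresholdAveraging:
    def test_identical_graphs_average_to_single_graph_pc(self, rng):
        adj, part = random_graph_and_partition(rng, 12, 3)
        from connseg.graph_build import BinaryGraphSet

        gs = BinaryGraphSet((0.1, 0.2, 0.3), (adj, adj, adj))
        mean_pc, per = threshold_averaged_pc(gs, part)
        single = participation_coefficient(adj, part)
        assert np.allclose(mean_pc, single)
        assert per.shape == (3, 12)

    def test_mean_equals_mean_of_independent_calls(self, rng):
        mat = rng.standard_normal((20, 20))
        mat = (mat + mat.T) / 2
        _, part = random_graph_and_partition(rng, 20, 3)
        gs = multi_threshold_graphs(mat)
        mean_pc, per = threshold_averaged_pc(gs, part)
        manual = np.mean(
            [participation_coefficient(a, part) for a in gs.adjacency], axis=0
        )
        assert np.allclose(mean_pc, manual)
        assert np.allclose(per.mean(axis=0), mean_pc)


class TestConnectionCounts:
    @pytest.fixture()
    def fixture_set(self, rng):
        mat = rng.standard_normal((20, 20))
        mat = (mat + mat.T) / 2
        _, part = random_graph_and_partition(rng, 20, 3)
        return multi_threshold_graphs(mat), part

    def test_all_internal_edges_give_zero_between(self):
        adj = _star_adjacency(6, 0, [1, 2, 3])
        part = ModularPartition(np.array([0, 0, 0, 0, 1, 1]))
        from connseg.graph_build import BinaryGraphSet

        gs = BinaryGraphSet((0.5,), (adj,))
        within, between = within_between_counts(gs, part, 0)
        assert within == 3.0 and between == 0.0

    def test_counts_sum_to_mean_degree(self, fixture_set):
        gs, part = fixture_set
        for node in range(part.n_nodes):
            table = module_connection_counts(gs, part, node)
            mean_degree = np.mean([a[node].sum() for a in gs.adjacency])
            assert table["mean_count"].sum() == pytest.approx(mean_degree)
            within, between = within_between_counts(gs, part, node)
            assert within + between == pytest.approx(mean_degree)

    def test_counts_reproduce_pc_per_threshold(self, fixture_set):
        """Algebraic consistency: PC recomputed from per-threshold k_i(m)
        matches the direct computation."""
        gs, part = fixture_set
        node = 5
        ind = part.indicator().astype(float)
        for adj in gs.adjacency:
            k_m = adj[node].astype(float) @ ind
            k = k_m.sum()
            pc_from_counts = 1 - np.sum((k_m / k) ** 2) if k else 0.0
            direct = participation_coefficient(adj, part)[node]
            assert pc_from_counts == pytest.approx(direct)


class TestHemisphereCounts:
    def test_neighbors_on_one_side_only(self, node_table, partition76):
        from connseg.graph_build import BinaryGraphSet

        n = 76
        adj = _star_adjacency(n, 0, [1, 2, 10])  # all-left neighbors
        gs = BinaryGraphSet((0.1,), (adj,))
        table = hemisphere_connection_counts(gs, partition76, 0, node_table)
        right = table[table["hemisphere"] == "R"]
        assert right["within"].iloc[0] == 0.0
        assert right["between"].iloc[0] == 0.0

    def test_left_plus_right_equals_whole_brain(self, rng, node_table, partition76):
        for seed in range(5):
            mat = np.random.default_rng(seed).standard_normal((76, 76))
            mat = (mat + mat.T) / 2
            gs = multi_threshold_graphs(mat)
            node = int(rng.integers(0, 76))
            per_hemi = hemisphere_connection_counts(gs, partition76, node, node_table)
            within, between = within_between_counts(gs, partition76, node)
            assert per_hemi["within"].sum() == pytest.approx(within)
            assert per_hemi["between"].sum() == pytest.approx(between)

    def test_matches_enumeration_oracle(self, node_table, partition76):
        rng = np.random.default_rng(99)
        mat = rng.standard_normal((76, 76))
        mat = (mat + mat.T) / 2
        gs = multi_threshold_graphs(mat)
        node = 3
        hemi = node_table.sort_values("node_id")["hemisphere"].to_numpy()
        own = partition76.module_of(node)
        table = hemisphere_connection_counts(gs, partition76, node, node_table)
        for h in ("L", "R"):
            w_counts, b_counts = [], []
            for adj in gs.adjacency:
                neighbors = [j for j in range(76) if adj[node, j]]
                w_counts.append(
                    sum(1 for j in neighbors
                        if hemi[j] == h and partition76.module_of(j) == own)
                )
                b_counts.append(
                    sum(1 for j in neighbors
                        if hemi[j] == h and partition76.module_of(j) != own)
                )
            row = table[table["hemisphere"] == h].iloc[0]
            assert row["within"] == pytest.approx(np.mean(w_counts))
            assert row["between"] == pytest.approx(np.mean(b_counts))

    def test_missing_hemisphere_errors(self, partition76, node_table):
        from connseg.graph_build import BinaryGraphSet

        broken = node_table.copy()
        broken.loc[0, "hemisphere"] = None
        adj = np.zeros((76, 76), dtype=bool)
        gs = BinaryGraphSet((0.1,), (adj,))
        with pytest.raises(ValueError, match="hemisphere"):
            hemisphere_connection_counts(gs, partition76, 0, broken)
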