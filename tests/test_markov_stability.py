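import itertools

import networkx as nx
import numpy as np
import pytest
from networkx.algorithms import community as nxc

from soilnet import markov_stability as ms


def graph_of(g: nx.Graph) -> ms.Graph:
    return ms.Graph.from_networkx(g)


def three_cliques() -> ms.Graph:
    return graph_of(
        nx.disjoint_union_all([nx.complete_graph(4) for _ in range(3)])
    )


class TestStabilityMatrix:
    def test_linearized_t1_equals_modularity_two_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        G = graph_of(g)
        b = ms.stability_matrix(G, 1.0, "linearized")
        part = ms.Partition(G.nodes, np.array([0, 0, 0, 1, 1, 1]))
        assert ms.partition_quality(b, part) == pytest.approx(0.5)

    @pytest.mark.parametrize("mode", ["linearized", "exponential"])
    @pytest.mark.parametrize("t", [0.0, 0.3, 1.0, 7.0])
    def test_all_in_one_partition_scores_zero(self, mode, t):
        G = three_cliques()
        b = ms.stability_matrix(G, t, mode)
        allone = ms.Partition(G.nodes, np.zeros(12, dtype=int))
        assert abs(ms.partition_quality(b, allone)) < 1e-12

    @pytest.mark.parametrize("mode", ["linearized", "exponential"])
    def test_t0_singletons_score_one_minus_pi_squared(self, mode):
        G = graph_of(nx.karate_club_graph())
        b = ms.stability_matrix(G, 0.0, mode)
        singles = ms.Partition(G.nodes, np.arange(G.n_nodes))
        expected = 1 - (G.stationary**2).sum()
        assert ms.partition_quality(b, singles) == pytest.approx(expected)

    def test_linearized_matches_independent_modularity(self):
        for seed in range(5):
            g = nx.gnp_random_graph(25, 0.2, seed=seed)
            g.remove_nodes_from(list(nx.isolates(g)))
            G = graph_of(g)
            b = ms.stability_matrix(G, 1.0, "linearized")
            part = ms.louvain_optimize(b, n_restarts=5, seed=seed,
                                       nodes=G.nodes)
            comms = [
                {int(v) for v in part.members(c)} for c in range(part.k)
            ]
            assert ms.partition_quality(b, part) == pytest.approx(
                nxc.modularity(g, comms), abs=1e-12
            )

    def test_exponential_linearized_agree_to_first_order(self):
        G = graph_of(nx.karate_club_graph())
        part = ms.Partition(G.nodes, np.arange(G.n_nodes) % 3)
        diffs = {}
        for t in (1e-3, 1e-4):
            d = ms.partition_quality(
                ms.stability_matrix(G, t, "exponential"), part
            ) - ms.partition_quality(
                ms.stability_matrix(G, t, "linearized"), part
            )
            diffs[t] = abs(d)
        # |R_exp - R_lin| = O(t^2): shrinking t by 10 shrinks the gap ~100x
        assert diffs[1e-4] < diffs[1e-3] / 50

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ms.stability_matrix(three_cliques(), -1.0)


class TestLouvain:
    def test_three_cliques_recovered_for_every_seed(self):
        G = three_cliques()
        b = ms.stability_matrix(G, 1.0, "linearized")
        for seed in range(20):
            part = ms.louvain_optimize(b, n_restarts=5, seed=seed,
                                       nodes=G.nodes)
            assert part.k == 3
            groups = {
                frozenset(part.members(c)) for c in range(3)
            }
            expected = {
                frozenset(str(v) for v in range(i, i + 4))
                for i in (0, 4, 8)
            }
            assert groups == expected

    def test_single_edge_graph_is_one_community(self):
        G = graph_of(nx.path_graph(2))
        b = ms.stability_matrix(G, 1.0, "linearized")
        part = ms.louvain_optimize(b, n_restarts=3, seed=0, nodes=G.nodes)
        assert part.k == 1

    def test_exhaustive_oracle_two_triangles(self):
        # enumerate all 203 partitions of 6 nodes; Louvain must attain the
        # global optimum of the t=1 linearized quality (= modularity)
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        G = graph_of(g)
        b = ms.stability_matrix(G, 1.0, "linearized")

        def partitions(seq):
            if not seq:
                yield []
                return
            head, *rest = seq
            for smaller in partitions(rest):
                for i, block in enumerate(smaller):
                    yield smaller[:i] + [block + [head]] + smaller[i + 1:]
                yield [[head]] + smaller

        best = -np.inf
        for blocks in partitions(list(range(6))):
            labels = np.empty(6, dtype=int)
            for c, block in enumerate(blocks):
                labels[block] = c
            q = ms.partition_quality(b, ms.Partition(G.nodes, labels))
            best = max(best, q)
        part = ms.louvain_optimize(b, n_restarts=10, seed=1, nodes=G.nodes)
        assert ms.partition_quality(b, part) == pytest.approx(best, abs=1e-12)

    def test_never_below_trivial_baselines(self, rng):
        for seed in range(5):
            g = nx.gnp_random_graph(20, 0.25, seed=seed)
            g.remove_nodes_from(list(nx.isolates(g)))
            G = graph_of(g)
            for t in (0.3, 1.0, 3.0):
                b = ms.stability_matrix(G, t, "linearized")
                part = ms.louvain_optimize(b, 5, seed, nodes=G.nodes)
                q = ms.partition_quality(b, part)
                allone = ms.Partition(G.nodes, np.zeros(G.n_nodes, int))
                singles = ms.Partition(G.nodes, np.arange(G.n_nodes))
                assert q >= ms.partition_quality(b, allone) - 1e-12
                assert q >= ms.partition_quality(b, singles) - 1e-12

    def test_planted_partition_recovered(self):
        probs = np.full((4, 4), 0.02)
        np.fill_diagonal(probs, 0.5)
        g = nx.stochastic_block_model([15] * 4, probs, seed=5)
        g.remove_nodes_from(list(nx.isolates(g)))
        G = graph_of(g)
        b = ms.stability_matrix(G, 1.0, "linearized")
        part = ms.louvain_optimize(b, 10, seed=0, nodes=G.nodes)
        from sklearn.metrics import adjusted_rand_score

        truth = [int(v) // 15 for v in G.nodes]
        assert adjusted_rand_score(truth, part.labels) >= 0.9


class TestVariationOfInformation:
    def test_identical_partitions_zero(self):
        p = ms.Partition(list("abcd"), np.array([0, 0, 1, 1]))
        assert ms.variation_of_information(p, p) == 0.0

    def test_singletons_vs_all_in_one_is_log_n(self):
        nodes = [str(i) for i in range(8)]
        singles = ms.Partition(nodes, np.arange(8))
        allone = ms.Partition(nodes, np.zeros(8, int))
        assert ms.variation_of_information(singles, allone) == pytest.approx(
            np.log(8)
        )

    def test_crossed_pairs_value(self):
        nodes = list("abcd")
        p1 = ms.Partition(nodes, np.array([0, 0, 1, 1]))  # {a,b | c,d}
        p2 = ms.Partition(nodes, np.array([0, 1, 0, 1]))  # {a,c | b,d}
        assert ms.variation_of_information(p1, p2) == pytest.approx(
            2 * np.log(2)
        )

    def test_node_mismatch_raises(self):
        p1 = ms.Partition(list("ab"), np.array([0, 1]))
        p2 = ms.Partition(list("ax"), np.array([0, 1]))
        with pytest.raises(ValueError):
            ms.variation_of_information(p1, p2)


class TestScanAndSelect:
    def test_disconnected_components_never_merge(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        G = graph_of(g)
        res = ms.scan_markov_times(
            G, np.logspace(-1, 2, 12), "exponential", n_restarts=5, seed=0
        )
        assert (res.community_counts >= 2).all()

    def test_single_time_grid_reduces_to_modularity(self):
        G = three_cliques()
        res = ms.scan_markov_times(G, [1.0], "linearized", 5, seed=0)
        assert res.community_counts[0] == 3

    def test_ring_of_cliques_coarsens_over_time(self):
        g = nx.ring_of_cliques(6, 4)
        G = graph_of(g)
        res = ms.scan_markov_times(
            G, np.logspace(-2, 2, 24), "exponential", n_restarts=5, seed=1
        )
        ks = res.community_counts
        q = len(ks) // 4
        assert ks[-q:].max() <= ks[:q].min()

    def test_run_length_oracle(self):
        # crafted k sequence (8,6,4,4,4,4,2,2): longest k>2 plateau is k=4
        nodes = [str(i) for i in range(10)]
        ks = [8, 6, 4, 4, 4, 4, 2, 2]
        partitions = [
            ms.Partition(nodes, np.arange(10) % k) for k in ks
        ]
        res = ms.StabilityResult(
            np.arange(1.0, 9.0), partitions, np.zeros(8),
            np.array(ks), "linearized", 1,
        )
        chosen = ms.select_partition(res)
        assert chosen.k == 4

    def test_no_k_above_two_raises(self):
        nodes = [str(i) for i in range(6)]
        partitions = [ms.Partition(nodes, np.arange(6) % 2)] * 3
        res = ms.StabilityResult(
            np.arange(1.0, 4.0), partitions, np.zeros(3),
            np.array([2, 2, 2]), "linearized", 1,
        )
        with pytest.raises(ValueError, match="k >= 3"):
            ms.select_partition(res)

    def test_selection_invariant_to_reversed_grid(self):
        G = graph_of(nx.ring_of_cliques(5, 4))
        res = ms.scan_markov_times(
            G, np.logspace(-1.5, 1.5, 20), "linearized", 5, seed=3
        )
        sel = ms.select_partition(res)
        rev = ms.StabilityResult(
            res.time_grid[::-1],
            res.partitions[::-1],
            res.stability[::-1],
            res.community_counts[::-1],
            res.mode,
            res.n_restarts,
            vi_matrix=res.vi_matrix[::-1, ::-1],
        )
        assert ms.select_partition(rev).k == sel.k

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            ms.scan_markov_times(
                ms.Graph([], np.zeros((0, 0))), [1.0], "linearized"
            )

    def test_isolated_nodes_dropped_with_warning(self):
        g = nx.complete_graph(3)
        g.add_node("loner")
        with pytest.warns(UserWarning, match="isolated"):
            G = ms.Graph.from_networkx(g)
        assert G.n_nodes == 3
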