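import itertools

import networkx as nx
import numpy as np
import pytest

from strictnet import (
    GeneNetwork,
    InteractionSet,
    ValidationError,
    background_proportion,
    call_central_genes,
    central_scores,
    chain_precision,
    clustering_coefficients,
    cluster_precision,
    compare_degrees,
    compare_density_permutation,
    compute_metrics,
    concat_datasets,
    graph_density,
    hub_precision,
    overlap_test,
    partition_network,
    simulate_network_counts,
    union_edges,
)
from strictnet.ggm import GGMConfig
from strictnet.metrics import _network_from_cells

from conftest import (
    all_graphs,
    as_network,
    brute_betweenness,
    brute_clustering,
    graph_from_adj,
)

class TestDensity:
    def test_reported_network_sizes(self):
        assert round(graph_density(57, 30), 3) == 0.019
        assert round(graph_density(74, 100), 3) == 0.037

    def test_complete_triangle(self):
        assert graph_density(3, 3) == 1.0

    def test_identity_with_edge_count(self):
        for v, e in [(5, 3), (12, 40), (57, 30)]:
            assert graph_density(v, e) * v * (v - 1) / 2 == pytest.approx(e)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValidationError):
            graph_density(1, 0)


class TestCentralScores:
    def test_path_of_three(self):
        scores = central_scores(as_network(nx.path_graph(3)))
        assert scores == {0: 0.0, 1: 1.0, 2: 0.0}

    def test_star_center_counts_leaf_pairs(self):
        scores = central_scores(as_network(nx.star_graph(3)))
        assert scores[0] == 3.0  # 3 leaf pairs route through the center

    def test_four_cycle_interior_half(self):
        scores = central_scores(as_network(nx.cycle_graph(4)))
        assert all(s == pytest.approx(0.5) for s in scores.values())

    @pytest.mark.parametrize("n_nodes", [4, 5])
    def test_matches_brute_force_on_all_small_graphs(self, n_nodes):
        for adj in all_graphs(n_nodes):
            got = central_scores(as_network(graph_from_adj(adj)))
            want = brute_betweenness(adj, n_nodes)
            for v in range(n_nodes):
                assert got[v] == pytest.approx(want[v], abs=1e-9)

    def test_tree_total_equals_interior_path_length(self, rng):
        """On a tree, sum c(v) = sum over pairs of (path length - 1)."""
        for _ in range(10):
            tree = nx.random_labeled_tree(rng.integers(4, 12), seed=int(rng.integers(1e6)))
            scores = central_scores(as_network(tree))
            lengths = dict(nx.all_pairs_shortest_path_length(tree))
            expected = sum(lengths[s][t] - 1
                           for s, t in itertools.combinations(tree.nodes, 2))
            assert sum(scores.values()) == pytest.approx(expected)


class TestClustering:
    def test_triangle_is_fully_clustered(self):
        cl, mean = clustering_coefficients(as_network(nx.complete_graph(3)))
        assert all(v == 1.0 for v in cl.values())
        assert mean == 1.0

    def test_path_has_no_triangles(self):
        cl, mean = clustering_coefficients(as_network(nx.path_graph(3)))
        assert all(v == 0.0 for v in cl.values())
        assert mean == 0.0

    def test_braced_square_hand_oracle(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")])
        cl, _ = clustering_coefficients(as_network(g))
        assert cl["a"] == pytest.approx(2 / 3)
        assert cl["b"] == 1.0

    def test_low_degree_nodes_excluded_from_network_mean(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        cl, mean = clustering_coefficients(as_network(g))
        assert cl["d"] == 0.0
        assert mean == pytest.approx((1 + 1 + 1 / 3) / 3)  # d has degree 1

    @pytest.mark.parametrize("n_nodes", [4, 5])
    def test_matches_triangle_counting_on_all_small_graphs(self, n_nodes):
        for adj in all_graphs(n_nodes):
            cl, _ = clustering_coefficients(as_network(graph_from_adj(adj)))
            want = brute_clustering(adj, n_nodes)
            for v in range(n_nodes):
                assert cl[v] == pytest.approx(want[v], abs=1e-12)


class TestCentralGeneCalls:
    def test_thresholds_are_strict(self):
        g = nx.star_graph(6)  # center degree 6, leaves 1
        metrics = compute_metrics(as_network(g))
        calls = {c.gene: c.called
                 for c in call_central_genes(metrics, degree_min=5, score_min=14)}
        assert calls[0]  # center: degree 6 > 5, score 15 > 14
        calls = {c.gene: c.called
                 for c in call_central_genes(metrics, degree_min=6, score_min=14)}
        assert not calls[0]  # degree 6 is not > 6
        calls = {c.gene: c.called
                 for c in call_central_genes(metrics, degree_min=5, score_min=15)}
        assert not calls[0]  # score 15 is not > 15

    def test_planted_hub_is_the_only_call(self):
        planted = hub_precision(10, 10, 0.3)
        dataset, _ = simulate_network_counts(4000, planted, seed=2)
        net = _network_from_cells(dataset, GGMConfig(), 2)
        metrics = compute_metrics(net)
        calls = [c.gene for c in call_central_genes(metrics, 5, 10) if c.called]
        assert calls == ["N0001"]  # the star center of the planted block


class TestCompareDegrees:
    def test_identical_sequences_are_null(self):
        net = as_network(nx.cycle_graph(6))
        _, p = compare_degrees(net, net, alternative="less")
        assert p >= 0.5

    def test_extreme_separation_matches_enumeration(self):
        empty = as_network(nx.empty_graph(5))
        full = as_network(nx.complete_graph(4))
        _, p = compare_degrees(empty, full, alternative="less")
        # all five zeros rank below all four threes; one-sided exact p = 1/C(9,5)
        assert p == pytest.approx(1 / 126)

    def test_isolated_universe_members_can_be_included(self):
        net_a = as_network(nx.complete_graph(3))
        net_b = as_network(nx.complete_graph(3))
        universe = [0, 1, 2, 10, 11]
        _, p_with = compare_degrees(net_a, net_b, universe=universe)
        assert 0 < p_with <= 1

    def test_empty_network_rejected(self):
        with pytest.raises(ValidationError):
            compare_degrees(as_network(nx.empty_graph(0)),
                            as_network(nx.path_graph(2)))


class TestPartition:
    def test_disjoint_triangles_recovered(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        labels = partition_network(as_network(g), n_clusters=2)
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]
        assert labels[0] != labels[3]

    def test_single_clique_is_one_cluster_below_height_one(self):
        labels = partition_network(as_network(nx.complete_graph(4), rho=0.6),
                                   height=0.9)
        assert len(set(labels.values())) == 1

    def test_components_never_merge_below_height_one(self):
        g = nx.disjoint_union(nx.path_graph(3), nx.path_graph(3))
        labels = partition_network(as_network(g, rho=0.9), height=0.99)
        assert labels[0] != labels[3]

    def test_planted_two_cluster_structure_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        planted = cluster_precision(10, 5, 0.25)
        dataset, _ = simulate_network_counts(4000, planted, seed=6)
        net = _network_from_cells(dataset, GGMConfig(), 6)
        labels = partition_network(net, n_clusters=2)
        truth = [0] * 5 + [1] * 5
        got = [labels[g] for g in sorted(net.graph.nodes)]
        assert adjusted_rand_score(truth, got) == 1.0


class TestOverlap:
    def test_background_proportion_small_cases(self):
        one = InteractionSet(pairs=frozenset({frozenset({"a", "b"})}), universe_size=2)
        assert background_proportion(one) == 1.0
        three = InteractionSet(pairs=frozenset({frozenset({"a", "b"}),
                                                frozenset({"b", "c"}),
                                                frozenset({"c", "d"})}),
                               universe_size=4)
        assert background_proportion(three) == 0.5

    def test_zero_overlap_is_certain(self):
        ref = InteractionSet(pairs=frozenset({frozenset({"x", "y"})}), universe_size=10)
        res = overlap_test([("a", "b"), ("b", "c")], ref)
        assert res.k_overlap == 0
        assert res.p == 1.0

    def test_three_edges_half_background(self):
        ref = InteractionSet(pairs=frozenset({frozenset({"a", "b"}),
                                              frozenset({"b", "c"}),
                                              frozenset({"c", "d"})}),
                             universe_size=4)
        # background 0.5; edges hit the reference twice out of 3
        res = overlap_test([("a", "b"), ("b", "c"), ("a", "c")], ref)
        assert res.k_overlap == 2
        assert res.p == pytest.approx(0.5)  # 4 of 8 equally likely outcomes

    def test_matches_full_outcome_enumeration(self):
        p0 = 0.3
        ref = InteractionSet(
            pairs=frozenset(frozenset({f"x{i}", f"y{i}"}) for i in range(12)),
            universe_size=100)
        for n, k in [(5, 2), (8, 5), (11, 7)]:
            # exhaustive enumeration of all 2^n hit/miss outcomes
            want = sum(p0 ** bin(bits).count("1") * (1 - p0) ** (n - bin(bits).count("1"))
                       for bits in range(2 ** n) if bin(bits).count("1") >= k)
            edges = [(f"x{i}", f"y{i}") for i in range(k)]
            edges += [(f"m{i}", f"n{i}") for i in range(n - k)]
            res = overlap_test(edges, ref, background_p=p0)
            assert res.p == pytest.approx(want, rel=1e-10)

    def test_union_edges_deduplicates_across_strata(self):
        a = as_network(nx.path_graph(3))
        b = as_network(nx.path_graph(3))
        assert len(union_edges([a, b])) == 2

    def test_empty_reference_rejected(self):
        ref = InteractionSet(pairs=frozenset(), universe_size=5)
        with pytest.raises(ValidationError):
            overlap_test([("a", "b")], ref)


class TestDensityPermutation:
    def _contrast_dataset(self, seed):
        planted = chain_precision(8, 0.5)
        planted.broken_fraction = 1.0
        planted.break_seed = seed
        control, _ = simulate_network_counts(600, planted, "control", seed=seed)
        case, _ = simulate_network_counts(600, planted, "case", seed=seed + 9000)
        return concat_datasets([control, case])

    def test_rejects_for_a_fully_broken_case(self):
        dataset = self._contrast_dataset(seed=4)
        res = compare_density_permutation(dataset, {"condition": "control"},
                                          {"condition": "case"},
                                          config=GGMConfig(min_cells=100),
                                          n_perm=99, seed=4)
        assert res["density_a"] > res["density_b"]
        assert res["p"] <= 0.05

    def test_homogeneous_halves_are_null(self):
        planted = chain_precision(8, 0.5)
        a, _ = simulate_network_counts(600, planted, "control", seed=21)
        b, _ = simulate_network_counts(600, planted, "control", seed=22)
        b.annotations.loc[:, "condition"] = "case"
        b.annotations.loc[:, "cell_id"] = ["k" + c for c in b.annotations["cell_id"]]
        b.cell_ids = b.annotations["cell_id"].to_numpy(dtype=object)
        dataset = concat_datasets([a, b])
        res = compare_density_permutation(dataset, {"condition": "control"},
                                          {"condition": "case"},
                                          config=GGMConfig(min_cells=100),
                                          n_perm=49, seed=21)
        assert res["p"] > 0.1

    def test_zero_permutations_rejected(self):
        dataset = self._contrast_dataset(seed=1)
        with pytest.raises(ValidationError):
            compare_density_permutation(dataset, {"condition": "control"},
                                        {"condition": "case"}, n_perm=0, seed=0)
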