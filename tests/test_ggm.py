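import numpy as np
import pytest

from strictnet import (
    GGMConfig,
    ValidationError,
    build_stratum_network,
    chain_precision,
    estimate_ggm,
    filter_genes,
    log_transform,
    pearson_matrix,
    simulate_network_counts,
)
from strictnet.containers import GeneSet
from strictnet.simulate import PlantedNetwork

from conftest import make_dataset


def edges_of(network):
    return {frozenset(e) for e in network.graph.edges()}


class TestFilterGenes:
    def test_detection_rule(self):
        counts = np.zeros((3, 100), dtype=int)
        counts[0, :50] = 1    # 50% detected -> kept
        counts[1, :5] = 1     # 5% -> dropped at 0.1
        kept = filter_genes(make_dataset(counts))
        assert kept == ["G0"]

    def test_threshold_boundary_is_inclusive(self):
        counts = np.zeros((1, 100), dtype=int)
        counts[0, :10] = 1    # exactly 10%
        assert filter_genes(make_dataset(counts)) == ["G0"]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            filter_genes(make_dataset([[1, 1]]), cell_mask=np.zeros(2, dtype=bool))


class TestTransformAndPearson:
    def test_log_transform_values(self):
        X = log_transform(np.array([[0, 1, 2]]))
        assert X[0, 0] == 0.0
        assert X[0, 1] == pytest.approx(np.log(2))
        assert X[0, 1] < X[0, 2]  # monotone

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            log_transform(np.array([[-1, 0]]))

    def test_perfect_correlations(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        r = pearson_matrix(np.vstack([x, 2 * x, -x]))
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_hand_fixture_matches_covariance_formula(self):
        X = np.array([[1.0, 2.0, 4.0], [2.0, 1.0, 3.0]])
        r = pearson_matrix(X)
        a, b = X
        expected = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        assert r[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_flagged_nan(self):
        r = pearson_matrix(np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))
        assert np.isnan(r[0, 1]) and np.isnan(r[1, 1])


class TestEstimateGGM:
    def test_two_gene_partial_equals_pearson(self, rng):
        # with no conditioning set the GGM edge weight is the correlation
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        X = rng.multivariate_normal([0, 0], cov, size=10_000).T
        config = GGMConfig(noise_correction=False)
        est, net = estimate_ggm(X, ["a", "b"], config, seed=0)
        r = pearson_matrix(X)[0, 1]
        assert net.graph.has_edge("a", "b")
        assert net.graph.edges["a", "b"]["partial_corr"] == pytest.approx(r, abs=1e-6)

    def test_chain_support_recovered_exactly(self):
        planted = chain_precision(5, 0.5)
        dataset, truth = simulate_network_counts(5000, planted, seed=12)
        X = log_transform(dataset.counts)
        _, net = estimate_ggm(X, dataset.gene_ids, seed=12, counts=dataset.counts)
        assert edges_of(net) == {frozenset(p) for p in truth.true_edges["control"]}

    def test_independence_null_is_nearly_empty(self):
        hits = 0
        for seed in range(5):
            planted = PlantedNetwork(precision=np.eye(10),
                                     gene_ids=[f"N{i}" for i in range(10)])
            dataset, _ = simulate_network_counts(3000, planted, seed=seed)
            _, net = estimate_ggm(log_transform(dataset.counts), dataset.gene_ids,
                                  seed=seed, counts=dataset.counts)
            hits += net.n_edges <= 1
        assert hits >= 4

    def test_edge_set_invariant_to_gene_ordering(self):
        planted = chain_precision(6, 0.4)
        dataset, _ = simulate_network_counts(3000, planted, seed=3)
        X = log_transform(dataset.counts)
        config = GGMConfig(lambda_=0.05)
        _, net = estimate_ggm(X, dataset.gene_ids, config, seed=0,
                              counts=dataset.counts)
        perm = np.array([3, 0, 5, 1, 4, 2])
        _, net_p = estimate_ggm(X[perm], dataset.gene_ids[perm], config, seed=0,
                                counts=dataset.counts[perm.tolist(), :])
        assert edges_of(net) == edges_of(net_p)

    def test_partial_correlations_are_bounded(self):
        planted = chain_precision(8, 0.45)
        dataset, _ = simulate_network_counts(2000, planted, seed=5)
        est, net = estimate_ggm(log_transform(dataset.counts), dataset.gene_ids,
                                seed=5, counts=dataset.counts)
        rho = est.partial_correlations()
        off = rho[~np.eye(8, dtype=bool)]
        assert np.all(np.abs(off) <= 1.0)
        for _, _, data in net.graph.edges(data=True):
            assert abs(data["partial_corr"]) <= 1.0

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValidationError):
            estimate_ggm(np.ones((3, 5)), ["a", "b", "c"])

    def test_single_gene_rejected(self):
        with pytest.raises(ValidationError):
            estimate_ggm(np.ones((1, 100)), ["a"])


class TestStratumNetwork:
    def test_control_network_denser_than_broken_case(self):
        planted = chain_precision(10, 0.5)
        planted.broken_fraction = 0.8
        control, _ = simulate_network_counts(2000, planted, "control", seed=8)
        case, _ = simulate_network_counts(2000, planted, "case", seed=1008)
        config = GGMConfig(min_cells=100)
        net_c = build_stratum_network(control, {"condition": "control"}, config, seed=0)
        net_k = build_stratum_network(case, {"condition": "case"}, config, seed=0)
        assert net_c.n_edges > net_k.n_edges

    def test_empty_selector_rejected(self):
        planted = chain_precision(4, 0.4)
        dataset, _ = simulate_network_counts(200, planted, "control", seed=0)
        with pytest.raises(ValidationError, match="cells"):
            build_stratum_network(dataset, {"condition": "case"})

    def test_gene_restriction_to_single_gene_rejected(self):
        planted = chain_precision(4, 0.4)
        dataset, _ = simulate_network_counts(300, planted, "control", seed=0)
        config = GGMConfig(min_cells=50,
                           genes=GeneSet("one", frozenset({"N0001"})))
        with pytest.raises(ValidationError, match="two genes"):
            build_stratum_network(dataset, {"condition": "control"}, config)
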