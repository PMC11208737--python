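import numpy as np
import pytest

from strictnet import (
    GeneSet,
    PlantedNetwork,
    SimulationConfig,
    Stratum,
    ValidationError,
    chain_precision,
    compute_specificity,
    cumulative_allele_frequency,
    hub_precision,
    simulate_celltype_counts,
    simulate_interactions,
    simulate_network_counts,
    simulate_variants,
)
from strictnet.caf import classify_lof


def _dense(dataset):
    return np.asarray(dataset.counts.todense())


class TestCelltypeCounts:
    def test_same_seed_is_bit_identical(self):
        config = SimulationConfig(n_genes=100, n_specific_per_type=5,
                                  strata=[Stratum(n_cells=100)], seed=11)
        a, _ = simulate_celltype_counts(config)
        b, _ = simulate_celltype_counts(config)
        assert (a.counts != b.counts).nnz == 0
        assert a.annotations.equals(b.annotations)

    def test_adding_a_stratum_leaves_the_first_untouched(self):
        base = dict(n_genes=100, n_specific_per_type=5, seed=11)
        one, _ = simulate_celltype_counts(
            SimulationConfig(strata=[Stratum(n_cells=80)], **base))
        two, _ = simulate_celltype_counts(
            SimulationConfig(strata=[Stratum(n_cells=80),
                                     Stratum(condition="case", n_cells=80)], **base))
        a = _dense(one)
        b = _dense(two)[:, :one.n_cells]
        assert np.array_equal(a, b)

    def test_no_planting_gives_uniform_specificity(self):
        config = SimulationConfig(n_genes=400, specificity_fold=1.0,
                                  n_specific_per_type=10,
                                  strata=[Stratum(n_cells=2000)], seed=0)
        dataset, truth = simulate_celltype_counts(config)
        spec = compute_specificity(dataset)
        planted = sorted(truth.specific_genes["monocyte"])
        idx = dataset.gene_index(planted)
        col = spec.cell_types.index("monocyte")
        # K=4 types: specificity of "specific" genes stays near 1/K
        assert spec.values[idx, col].mean() == pytest.approx(0.25, abs=0.03)

    def test_strong_planting_concentrates_specificity(self):
        config = SimulationConfig(n_genes=400, specificity_fold=50.0,
                                  n_specific_per_type=10,
                                  strata=[Stratum(n_cells=2000)], seed=0)
        dataset, truth = simulate_celltype_counts(config)
        spec = compute_specificity(dataset)
        for k, cell_type in enumerate(spec.cell_types):
            idx = dataset.gene_index(sorted(truth.specific_genes[cell_type]))
            assert spec.values[idx, k].mean() > 0.9

    def test_degenerate_proportions_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(cell_type_proportions={"a": 0.5, "b": 0.2})
        with pytest.raises(ValidationError):
            SimulationConfig(cell_type_proportions={})

    def test_fold_below_one_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(specificity_fold=0.5)


class TestNetworkCounts:
    def test_identity_precision_gives_no_partial_correlation(self):
        planted = PlantedNetwork(precision=np.eye(8),
                                 gene_ids=[f"N{i}" for i in range(8)])
        dataset, _ = simulate_network_counts(5000, planted, seed=4)
        X = np.log1p(_dense(dataset))
        prec = np.linalg.inv(np.corrcoef(X))
        d = np.sqrt(np.diag(prec))
        rho = -prec / np.outer(d, d)
        np.fill_diagonal(rho, 0.0)
        assert np.abs(rho).max() < 0.05

    def test_chain_marginal_correlation_decays_with_distance(self):
        planted = chain_precision(5, 0.5)
        dataset, _ = simulate_network_counts(5000, planted, seed=4)
        r = np.corrcoef(np.log1p(_dense(dataset)))
        neighbors = np.mean([r[i, i + 1] for i in range(4)])
        assert neighbors > r[0, 4]

    def test_fully_broken_case_is_independent(self):
        planted = chain_precision(6, 0.5)
        planted.broken_fraction = 1.0
        assert planted.true_edges("case") == set()
        dataset, _ = simulate_network_counts(5000, planted, "case", seed=9)
        prec = np.linalg.inv(np.corrcoef(np.log1p(_dense(dataset))))
        d = np.sqrt(np.diag(prec))
        rho = -prec / np.outer(d, d)
        np.fill_diagonal(rho, 0.0)
        assert np.abs(rho).max() < 0.05

    def test_broken_fraction_removes_the_right_share_of_edges(self):
        planted = hub_precision(20, 10, 0.3)
        planted.broken_fraction = 0.5
        intact = planted.true_edges("control")
        broken = planted.true_edges("case")
        assert broken < intact
        assert len(broken) == len(intact) - round(0.5 * len(intact))

    def test_non_positive_definite_rejected(self):
        omega = np.array([[1.0, 0.99], [0.99, 0.5]])
        with pytest.raises(ValidationError):
            PlantedNetwork(precision=omega - 0.6 * np.eye(2), gene_ids=["a", "b"])

    def test_seed_determinism(self):
        planted = chain_precision(4, 0.4)
        a, _ = simulate_network_counts(50, planted, seed=7)
        b, _ = simulate_network_counts(50, planted, seed=7)
        assert (a.counts != b.counts).nnz == 0


class TestVariants:
    def test_zero_lof_fraction_gives_zero_caf(self):
        genes = GeneSet("g", frozenset({"A", "B", "C"}))
        table = simulate_variants(genes, 10, lof_fraction=0.0, seed=0)
        assert not table.records["consequence"].map(classify_lof).any()
        result = cumulative_allele_frequency(table, genes)
        assert result.aggregate_caf == 0.0

    def test_full_lof_caf_matches_hand_formula(self):
        genes = GeneSet("g", frozenset({"A"}))
        table = simulate_variants(genes, 5, lof_fraction=1.0, seed=0)
        afs = table.records["af"].to_numpy()
        result = cumulative_allele_frequency(table, genes, af_cutoff=1.0)
        assert result.aggregate_caf == pytest.approx(1 - np.prod(1 - afs), abs=1e-12)

    def test_seed_determinism(self):
        genes = GeneSet("g", frozenset({"A", "B"}))
        a = simulate_variants(genes, 6, seed=5)
        b = simulate_variants(genes, 6, seed=5)
        assert a.records.equals(b.records)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValidationError):
            GeneSet("g", frozenset())


class TestInteractions:
    def test_no_decoys_returns_exactly_true_edges(self):
        edges = {frozenset({"A", "B"}), frozenset({"B", "C"})}
        ref = simulate_interactions(edges, n_decoys=0, universe_size=10, seed=0)
        assert ref.pairs == frozenset(edges)

    def test_counts_match_request(self):
        edges = {frozenset({"A", "B"})}
        ref = simulate_interactions(edges, n_decoys=7, universe_size=50, seed=0)
        assert len(ref) == 8

    def test_saturated_universe_gives_background_one(self):
        from strictnet import background_proportion
        edges = {frozenset({"A", "B"})}
        ref = simulate_interactions(edges, n_decoys=2, universe_size=3, seed=0,
                                    universe_genes=["A", "B", "C"])
        assert background_proportion(ref) == 1.0
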