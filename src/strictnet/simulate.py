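"""Synthetic single-cell data with known ground truth.

Two count generators cover the two estimands of the pipeline:

* :func:`simulate_celltype_counts` draws negative-binomial counts per cell
  type with a planted fold-change ``f`` for cell-type-specific genes, so
  the specificity/enrichment stage has a known answer.
* :func:`simulate_network_counts` draws Poisson-lognormal counts whose
  latent Gaussian layer has a planted sparse precision matrix, so the
  graphical-model stage has a known edge set.  Conditional independence
  lives in the latent layer; ``log1p`` of the counts approximates it.

Variant tables and reference interaction sets are generated with planted
loss-of-function content and decoy pairs respectively.

All randomness flows through ``numpy.random.default_rng`` seeded from a
``SeedSequence``; each stratum gets an independent spawned substream so
adding a stratum never perturbs another.  Fixed seed implies bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    ExpressionDataset,
    GeneSet,
    InteractionSet,
    ValidationError,
    VariantTable,
)

#: consequence vocabulary used by the variant simulator
LOF_CONSEQUENCES = (
    "start_lost",
    "stop_gained",
    "stop_lost",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "frameshift_variant",
)
NON_LOF_CONSEQUENCES = (
    "missense_variant",
    "synonymous_variant",
    "intron_variant",
    "3_prime_UTR_variant",
)


@dataclass
class Stratum:
    """One block of cells sharing condition / age group / inflammation."""

    condition: str = "control"
    age_group: str = "adult"
    inflammation: str = "NA"
    n_cells: int = 2000
    n_donors: int = 4

    @property
    def label(self) -> str:
        return f"{self.condition}-{self.age_group}-{self.inflammation}"


@dataclass
class SimulationConfig:
    """Parameters of the cell-type count simulation.

    ``cell_type_proportions`` is a simplex over cell types; each planted
    specific gene has its negative-binomial mean multiplied by
    ``specificity_fold`` in its target type only.
    """

    n_genes: int = 1000
    cell_type_proportions: dict = field(
        default_factory=lambda: {
            "monocyte": 0.25, "t_helper": 0.25, "epithelial": 0.25, "ilc3": 0.25,
        }
    )
    n_specific_per_type: int = 25
    specificity_fold: float = 20.0
    baseline_log_mean: float = 0.0   # lognormal mu0 of per-gene NB means
    baseline_log_sd: float = 1.0     # lognormal sigma0
    dispersion: float = 2.0          # NB size parameter; var = m + m^2/size
    strata: list = field(default_factory=lambda: [Stratum()])
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.array(list(self.cell_type_proportions.values()), dtype=float)
        if len(props) == 0:
            raise ValidationError("at least one cell type is required")
        if np.any(props <= 0) or not np.isclose(props.sum(), 1.0):
            raise ValidationError("cell_type_proportions must be positive and sum to 1")
        if self.specificity_fold < 1:
            raise ValidationError("specificity_fold must be >= 1")
        k = len(self.cell_type_proportions)
        if k * self.n_specific_per_type > self.n_genes:
            raise ValidationError("not enough genes for the requested specific genes")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    specific_genes: dict = field(default_factory=dict)   # cell type -> set of symbols
    true_edges: dict = field(default_factory=dict)       # condition -> set of frozenset pairs
    lof_caf: dict = field(default_factory=dict)          # gene set name -> CAF

    def to_jsonable(self) -> dict:
        return {
            "specific_genes": {t: sorted(g) for t, g in self.specific_genes.items()},
            "true_edges": {
                c: sorted(tuple(sorted(p)) for p in e) for c, e in self.true_edges.items()
            },
            "lof_caf": dict(self.lof_caf),
        }


def _gene_names(n: int, prefix: str = "G") -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"{prefix}{i:0{width}d}" for i in range(1, n + 1)], dtype=object)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    """Gamma-Poisson mixture: variance = mean + mean^2 / size."""
    lam = rng.gamma(shape=size, scale=mean / size)
    return rng.poisson(lam)


def simulate_celltype_counts(config: SimulationConfig) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Draw NB counts per cell type with planted specific genes.

    Specific genes for cell type k are the k-th block of
    ``n_specific_per_type`` genes; their NB mean is multiplied by
    ``specificity_fold`` in that type.  Returns the dataset and the truth
    mapping each cell type to its planted genes.
    """
    types = list(config.cell_type_proportions)
    props = np.array([config.cell_type_proportions[t] for t in types])
    genes = _gene_names(config.n_genes)

    root = np.random.SeedSequence(config.seed)
    base_rng = np.random.default_rng(root.spawn(1)[0])
    base_mean = np.exp(base_rng.normal(config.baseline_log_mean,
                                       config.baseline_log_sd, config.n_genes))

    truth = SyntheticTruth()
    fold = np.ones((config.n_genes, len(types)))
    for k, cell_type in enumerate(types):
        lo = k * config.n_specific_per_type
        hi = lo + config.n_specific_per_type
        fold[lo:hi, k] = config.specificity_fold
        truth.specific_genes[cell_type] = set(genes[lo:hi])

    stratum_seeds = root.spawn(1 + len(config.strata))[1:]
    blocks, annotations = [], []
    for stratum, seq in zip(config.strata, stratum_seeds):
        rng = np.random.default_rng(seq)
        n_per_type = rng.multinomial(stratum.n_cells, props)
        for k, cell_type in enumerate(types):
            n = int(n_per_type[k])
            if n == 0:
                continue
            mean = np.broadcast_to((base_mean * fold[:, k])[:, None],
                                   (config.n_genes, n))
            blocks.append(_nb_counts(rng, mean, config.dispersion))
            donors = [f"{stratum.label}-d{i % stratum.n_donors}" for i in range(n)]
            annotations.append(pd.DataFrame({
                "cell_type": cell_type,
                "main_type": "immune" if cell_type != "epithelial" else "epithelial",
                "condition": stratum.condition,
                "age_group": stratum.age_group,
                "inflammation": stratum.inflammation,
                "donor": donors,
            }))

    counts = np.concatenate(blocks, axis=1)
    ann = pd.concat(annotations, ignore_index=True)
    ann.insert(0, "cell_id", [f"C{i:06d}" for i in range(len(ann))])
    dataset = ExpressionDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=genes,
        cell_ids=ann["cell_id"].to_numpy(dtype=object),
        annotations=ann,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# planted precision matrices


def _support_edges(precision: np.ndarray) -> set:
    m = precision.shape[0]
    return {
        frozenset((i, j))
        for i in range(m) for j in range(i + 1, m)
        if precision[i, j] != 0
    }


def _ensure_pd(omega: np.ndarray) -> np.ndarray:
    """Diagonal loading: omega + (|lambda_min| + 0.1) I when not PD."""
    lam_min = np.linalg.eigvalsh(omega).min()
    if lam_min <= 1e-8:
        omega = omega + (abs(lam_min) + 0.1) * np.eye(omega.shape[0])
    return omega


@dataclass
class PlantedNetwork:
    """A sparse precision matrix over network genes, with a broken variant.

    ``broken_fraction`` of the off-diagonal support is zeroed for the
    "case" condition, emulating a disease network whose connections are
    lost.  Positive definiteness after breaking is restored by diagonal
    loading when needed.
    """

    precision: np.ndarray
    gene_ids: np.ndarray
    broken_fraction: float = 0.0
    break_seed: int = 0

    def __post_init__(self) -> None:
        omega = np.asarray(self.precision, dtype=float)
        if not np.allclose(omega, omega.T):
            raise ValidationError("precision matrix must be symmetric")
        if np.linalg.eigvalsh(omega).min() <= 0:
            raise ValidationError("precision matrix must be positive definite")
        if not 0 <= self.broken_fraction <= 1:
            raise ValidationError("broken_fraction must be in [0,1]")
        self.precision = omega
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)

    @property
    def n_genes(self) -> int:
        return self.precision.shape[0]

    def precision_for(self, condition: str) -> np.ndarray:
        if condition != "case" or self.broken_fraction == 0:
            return self.precision.copy()
        rng = np.random.default_rng(np.random.SeedSequence((self.break_seed, 911)))
        edges = sorted(tuple(sorted(e)) for e in _support_edges(self.precision))
        n_break = int(round(self.broken_fraction * len(edges)))
        broken = rng.choice(len(edges), size=n_break, replace=False)
        omega = self.precision.copy()
        for idx in broken:
            i, j = edges[idx]
            omega[i, j] = omega[j, i] = 0.0
        return _ensure_pd(omega)

    def true_edges(self, condition: str = "control") -> set:
        omega = self.precision_for(condition)
        return {
            frozenset((self.gene_ids[i], self.gene_ids[j]))
            for pair in _support_edges(omega)
            for i, j in [tuple(pair)]
        }


def chain_precision(m: int, partial_corr: float = 0.5,
                    gene_prefix: str = "N") -> PlantedNetwork:
    """Tridiagonal precision: gene i partially correlated with i+1."""
    omega = np.eye(m)
    for i in range(m - 1):
        omega[i, i + 1] = omega[i + 1, i] = -partial_corr
    return PlantedNetwork(precision=_ensure_pd(omega), gene_ids=_gene_names(m, gene_prefix))


def hub_precision(m: int, hub_size: int = 10, partial_corr: float = 0.3,
                  gene_prefix: str = "N") -> PlantedNetwork:
    """Block-diagonal stars: every ``hub_size`` genes share one hub node."""
    if m % hub_size:
        raise ValidationError("m must be a multiple of hub_size")
    omega = np.eye(m)
    for start in range(0, m, hub_size):
        for leaf in range(start + 1, start + hub_size):
            omega[start, leaf] = omega[leaf, start] = -partial_corr
    return PlantedNetwork(precision=_ensure_pd(omega), gene_ids=_gene_names(m, gene_prefix))


def cluster_precision(m: int, cluster_size: int = 5, partial_corr: float = 0.2,
                      gene_prefix: str = "N") -> PlantedNetwork:
    """Block-diagonal cliques: all pairs within a block are connected."""
    if m % cluster_size:
        raise ValidationError("m must be a multiple of cluster_size")
    omega = np.eye(m)
    for start in range(0, m, cluster_size):
        block = slice(start, start + cluster_size)
        omega[block, block] = -partial_corr
    np.fill_diagonal(omega, 1.0)
    return PlantedNetwork(precision=_ensure_pd(omega), gene_ids=_gene_names(m, gene_prefix))


def simulate_network_counts(
    n_cells: int,
    planted: PlantedNetwork,
    condition: str = "control",
    seed: int = 0,
    *,
    log_mean: float = np.log(10.0),
    latent_scale: float = 0.8,
    age_group: str = "adult",
    inflammation: str = "NA",
    cell_type: str = "monocyte",
    n_donors: int = 4,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Poisson-lognormal counts with a planted latent precision matrix.

    The latent layer is ``z ~ MVN(0, Omega^{-1})`` standardized to unit
    marginal variance (partial correlations are invariant to that diagonal
    rescaling); counts are ``Poisson(exp(log_mean + latent_scale * z))``.
    ``condition="case"`` samples from the broken precision matrix.
    """
    omega = planted.precision_for(condition)
    sigma = np.linalg.inv(omega)
    scale = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(scale, scale)

    rng = np.random.default_rng(np.random.SeedSequence((seed, 101)))
    z = rng.multivariate_normal(np.zeros(planted.n_genes), corr,
                                size=n_cells, method="cholesky")
    lam = np.exp(log_mean + latent_scale * z)
    counts = rng.poisson(lam).T  # genes x cells

    ann = pd.DataFrame({
        "cell_id": [f"{condition}-{inflammation}-C{i:06d}" for i in range(n_cells)],
        "cell_type": cell_type,
        "main_type": "immune",
        "condition": condition,
        "age_group": age_group,
        "inflammation": inflammation,
        "donor": [f"{condition}-d{i % n_donors}" for i in range(n_cells)],
    })
    dataset = ExpressionDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=planted.gene_ids.copy(),
        cell_ids=ann["cell_id"].to_numpy(dtype=object),
        annotations=ann,
    )
    truth = SyntheticTruth(true_edges={condition: planted.true_edges(condition)})
    return dataset, truth


def simulate_variants(
    gene_set: GeneSet,
    n_variants_per_gene: int = 10,
    af_distribution=None,
    lof_fraction: float = 0.3,
    seed: int = 0,
) -> VariantTable:
    """Variant table with a planted fraction of loss-of-function consequences.

    Each gene receives exactly ``round(lof_fraction * n_variants_per_gene)``
    LoF variants; allele frequencies are drawn from ``af_distribution``
    (a frozen scipy distribution bounded in (0,1); default Beta(0.5, 30),
    a rare-variant-heavy spectrum).
    """
    if len(gene_set) == 0:
        raise ValidationError("gene set is empty")
    if not 0 <= lof_fraction <= 1:
        raise ValidationError("lof_fraction must be in [0,1]")
    if af_distribution is None:
        from scipy import stats
        af_distribution = stats.beta(0.5, 30.0)

    rng = np.random.default_rng(np.random.SeedSequence((seed, 202)))
    n_lof = int(round(lof_fraction * n_variants_per_gene))
    rows = []
    for gene in gene_set:  # sorted iteration for determinism
        is_lof = np.zeros(n_variants_per_gene, dtype=bool)
        is_lof[:n_lof] = True
        rng.shuffle(is_lof)
        afs = np.clip(af_distribution.rvs(n_variants_per_gene, random_state=rng),
                      1e-12, 1 - 1e-12)
        lof_cycle = non_cycle = 0
        for v in range(n_variants_per_gene):
            if is_lof[v]:
                cons = LOF_CONSEQUENCES[lof_cycle % len(LOF_CONSEQUENCES)]
                lof_cycle += 1
            else:
                cons = NON_LOF_CONSEQUENCES[non_cycle % len(NON_LOF_CONSEQUENCES)]
                non_cycle += 1
            rows.append((gene, f"{gene}_v{v + 1}", cons, float(afs[v])))
    table = pd.DataFrame(rows, columns=["gene", "variant_id", "consequence", "af"])
    return VariantTable(records=table)


def simulate_interactions(
    true_edges: set,
    n_decoys: int = 0,
    universe_size: int = 19566,
    seed: int = 0,
    universe_genes=None,
) -> InteractionSet:
    """Reference interaction set = planted edges plus decoy non-edge pairs.

    Decoys are sampled uniformly (by rejection) from pairs of a gene
    universe of ``universe_size`` symbols that are not planted edges; the
    default universe is the planted genes padded with background symbols.
    """
    true_edges = {frozenset(p) for p in true_edges}
    if universe_genes is None:
        core = sorted({g for pair in true_edges for g in pair})
        if len(core) > universe_size:
            raise ValidationError("universe_size smaller than the planted gene count")
        universe_genes = core + [f"BG{i:05d}" for i in range(universe_size - len(core))]
    universe_genes = list(universe_genes)
    if len(universe_genes) != universe_size:
        raise ValidationError("universe_genes length must equal universe_size")

    max_pairs = universe_size * (universe_size - 1) // 2
    if len(true_edges) + n_decoys > max_pairs:
        raise ValidationError("more pairs requested than the universe contains")

    rng = np.random.default_rng(np.random.SeedSequence((seed, 303)))
    decoys: set = set()
    while len(decoys) < n_decoys:
        i, j = rng.integers(0, universe_size, size=2)
        if i == j:
            continue
        pair = frozenset((universe_genes[i], universe_genes[j]))
        if pair in true_edges or pair in decoys:
            continue
        decoys.add(pair)
    return InteractionSet(pairs=frozenset(true_edges | decoys), universe_size=universe_size)
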