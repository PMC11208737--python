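"""Expression-weighted cell-type enrichment and cell-composition tests.

Specificity of gene g in cell type t is the mean expression of g in t
divided by the sum of g's mean expressions over all types, so each
expressed gene's specificities sum to 1 across types.  Enrichment of a
target gene set in a type is tested by bootstrap: the observed mean
specificity of the targets is compared against the means of random
equal-size gene lists drawn uniformly from all expressed genes, and the
empirical upper-tail p-values are FDR-adjusted (Benjamini-Hochberg)
across cell types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionDataset, GeneSet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SpecificityMatrix:
    """Per-gene, per-cell-type expression specificity.

    ``values[g, t] = mean_t(g) / sum_t' mean_t'(g)``; rows of genes with
    zero total expression are zero and flagged in ``expressed``.
    """

    values: np.ndarray          # genes x cell types, entries in [0,1]
    gene_ids: np.ndarray
    cell_types: list
    expressed: np.ndarray       # bool per gene: nonzero total mean

    def __post_init__(self) -> None:
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValidationError("specificity entries must lie in [0,1]")
        row_sums = self.values[self.expressed].sum(axis=1)
        if self.expressed.any() and not np.allclose(row_sums, 1.0):
            raise ValidationError("expressed specificity rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_types)


@dataclass
class EnrichmentResult:
    """Bootstrap enrichment of a gene set in one cell type."""

    cell_type: str
    observed: float     # mean specificity of the target genes
    p: float            # add-one bootstrap upper-tail p
    q: float            # Benjamini-Hochberg FDR across cell types
    n_boot: int


@dataclass
class ProportionTest:
    """Fisher's exact test on a (type vs other) x (case vs control) table."""

    cell_type: str
    table: np.ndarray   # [[case_type, case_other], [control_type, control_other]]
    odds_ratio: float
    p: float


def compute_specificity(
    dataset: ExpressionDataset,
    type_field: str = "cell_type",
    normalize: str = "raw",
) -> SpecificityMatrix:
    """Mean expression per type, row-normalized to specificity.

    ``type_field`` selects the annotation column defining cell types
    (subtype/state level by default, ``"main_type"`` for coarse types).
    ``normalize="cpm"`` rescales each cell to counts-per-million before
    averaging; the default uses raw mean counts, matching the plain ratio
    definition of specificity.
    """
    if type_field not in dataset.annotations.columns:
        raise ValidationError(f"unknown annotation field: {type_field!r}")
    labels = dataset.annotations[type_field].to_numpy()
    cell_types = sorted(set(labels))
    if len(cell_types) < 2:
        raise ValidationError("specificity requires at least two cell types")

    counts = dataset.counts.astype(float)
    if normalize == "cpm":
        totals = np.asarray(counts.sum(axis=0)).ravel()
        totals[totals == 0] = 1.0
        counts = counts.multiply(1e6 / totals).tocsr()
    elif normalize != "raw":
        raise ValidationError(f"unknown normalization: {normalize!r}")

    means = np.empty((dataset.n_genes, len(cell_types)))
    for t, cell_type in enumerate(cell_types):
        idx = np.flatnonzero(labels == cell_type)
        means[:, t] = np.asarray(counts[:, idx].mean(axis=1)).ravel()

    totals = means.sum(axis=1)
    expressed = totals > 0
    values = np.zeros_like(means)
    values[expressed] = means[expressed] / totals[expressed, None]
    return SpecificityMatrix(values=values, gene_ids=dataset.gene_ids.copy(),
                             cell_types=cell_types, expressed=expressed)


def bootstrap_enrichment(
    spec: SpecificityMatrix,
    targets: GeneSet,
    n_boot: int = 10_000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Bootstrap test of target-set specificity per cell type.

    Random gene lists of the same size are drawn uniformly, without
    replacement within a list, from all expressed genes; the upper-tail
    p-value uses the add-one rule ``p = (1 + #{boot >= obs}) / (n_boot+1)``
    so p is never exactly zero.  q-values are Benjamini-Hochberg across
    cell types.
    """
    pool = np.flatnonzero(spec.expressed)
    gene_pos = {g: i for i, g in enumerate(spec.gene_ids)}
    target_idx = np.array(
        [gene_pos[g] for g in sorted(targets.genes)
         if g in gene_pos and spec.expressed[gene_pos[g]]],
        dtype=int,
    )
    dropped = len(targets) - len(target_idx)
    if dropped:
        logger.info("bootstrap_enrichment: %d target genes absent or unexpressed", dropped)
    if len(target_idx) == 0:
        raise ValidationError("no overlap between targets and expressed matrix genes")
    n_target = len(target_idx)

    observed = spec.values[target_idx].mean(axis=0)

    rng = np.random.default_rng(np.random.SeedSequence((seed, 404)))
    pool_values = spec.values[pool]
    # Gumbel top-k trick gives n_boot without-replacement draws vectorized
    boot_sums = np.zeros((n_boot, spec.values.shape[1]))
    chunk = max(1, int(1e7 // max(len(pool), 1)))  # bound transient memory
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        keys = rng.random((stop - start, len(pool)))
        pick = np.argpartition(keys, n_target - 1, axis=1)[:, :n_target]
        boot_sums[start:stop] = pool_values[pick].sum(axis=1)
    boot_means = boot_sums / n_target

    ps = (1 + (boot_means >= observed[None, :]).sum(axis=0)) / (n_boot + 1)
    qs = multipletests(ps, method="fdr_bh")[1]
    return [
        EnrichmentResult(cell_type=t, observed=float(observed[i]), p=float(ps[i]),
                         q=float(qs[i]), n_boot=n_boot)
        for i, t in enumerate(spec.cell_types)
    ]


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.cell_type, r.observed, r.p, r.q, r.n_boot) for r in results],
        columns=["cell_type", "observed", "p", "q", "n_boot"],
    )


def compare_proportions(dataset: ExpressionDataset, cell_type: str,
                        type_field: str = "cell_type") -> ProportionTest:
    """Fisher's exact test for a shift in a cell type's abundance.

    Builds the 2x2 table of (cells of the type, other cells) x (case,
    control) and runs the two-sided exact test.
    """
    ann = dataset.annotations
    labels = ann[type_field].to_numpy()
    condition = ann["condition"].to_numpy()
    table = np.array([
        [int(((labels == cell_type) & (condition == "case")).sum()),
         int(((labels != cell_type) & (condition == "case")).sum())],
        [int(((labels == cell_type) & (condition == "control")).sum()),
         int(((labels != cell_type) & (condition == "control")).sum())],
    ])
    if table[0].sum() == 0 or table[1].sum() == 0:
        raise ValidationError("both conditions must contain cells")
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    return ProportionTest(cell_type=cell_type, table=table,
                          odds_ratio=float(odds_ratio), p=float(p))
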