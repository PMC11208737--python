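"""In-memory containers shared by every stage of the pipeline.

The central object is :class:`ExpressionDataset`: a genes x cells matrix of
raw read counts with one annotation record per cell (cell type, condition,
age group, inflammation status, donor).  Gene identity throughout the
package is the bare, case-sensitive symbol string; no alias resolution is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.sparse as sp

CONDITIONS = ("case", "control")
AGE_GROUPS = ("fetal", "pediatric", "adult")
INFLAMMATION = ("inflamed", "non_inflamed", "NA")

#: columns every cell-annotation table must carry, in canonical order
ANNOTATION_COLUMNS = (
    "cell_id",
    "cell_type",
    "main_type",
    "condition",
    "age_group",
    "inflammation",
    "donor",
)


class ValidationError(ValueError):
    """Raised when an input file or container violates its invariants."""


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


@dataclass
class ExpressionDataset:
    """Raw read counts (genes x cells) plus per-cell annotations.

    Parameters
    ----------
    counts
        Sparse or dense nonnegative integer matrix, one row per gene and
        one column per cell.
    gene_ids
        Unique gene symbols, length = number of rows.
    cell_ids
        Unique cell identifiers, length = number of columns.
    annotations
        DataFrame with the columns of :data:`ANNOTATION_COLUMNS`, one row
        per cell, aligned with ``cell_ids``.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        _check(len(self.gene_ids) == n_genes,
               f"gene_ids has {len(self.gene_ids)} entries but counts has {n_genes} rows")
        _check(len(self.cell_ids) == n_cells,
               f"cell_ids has {len(self.cell_ids)} entries but counts has {n_cells} columns")
        _check(n_genes > 0, "dataset must contain at least one gene")
        _check(n_cells > 0, "dataset must contain at least one cell")
        _check(len(set(self.gene_ids)) == n_genes, "gene_ids contain duplicates")
        _check(len(set(self.cell_ids)) == n_cells, "cell_ids contain duplicates")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be nonnegative")
        ann = self.annotations
        missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
        _check(not missing, f"annotations missing columns: {missing}")
        _check(len(ann) == n_cells,
               f"annotations has {len(ann)} rows but counts has {n_cells} columns")
        _check(list(ann["cell_id"]) == list(self.cell_ids),
               "annotations cell_id order does not match cell_ids")
        bad_cond = set(ann["condition"]) - set(CONDITIONS)
        _check(not bad_cond, f"unknown condition values: {sorted(bad_cond)}")
        bad_age = set(ann["age_group"]) - set(AGE_GROUPS)
        _check(not bad_age, f"unknown age_group values: {sorted(bad_age)}")
        bad_infl = set(ann["inflammation"]) - set(INFLAMMATION)
        _check(not bad_infl, f"unknown inflammation values: {sorted(bad_infl)}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices of the given symbols (missing symbols are skipped)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def cell_mask(self, **selectors: str) -> np.ndarray:
        """Boolean mask over cells matching all annotation selectors.

        ``dataset.cell_mask(condition="case", age_group="pediatric")``
        """
        mask = np.ones(self.n_cells, dtype=bool)
        for key, value in selectors.items():
            if key not in self.annotations.columns:
                raise ValidationError(f"unknown annotation field: {key!r}")
            mask &= (self.annotations[key] == value).to_numpy()
        return mask

    def subset_cells(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionDataset(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids[idx],
            annotations=self.annotations.iloc[idx].reset_index(drop=True),
        )

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
            and list(self.gene_ids) == list(other.gene_ids)
            and list(self.cell_ids) == list(other.cell_ids)
            and self.annotations[list(ANNOTATION_COLUMNS)].equals(
                other.annotations[list(ANNOTATION_COLUMNS)]
            )
        )


def concat_datasets(datasets) -> "ExpressionDataset":
    """Concatenate datasets cell-wise; gene catalogs must match exactly."""
    datasets = list(datasets)
    _check(len(datasets) > 0, "nothing to concatenate")
    first = datasets[0]
    for other in datasets[1:]:
        _check(list(other.gene_ids) == list(first.gene_ids),
               "datasets must share an identical gene catalog")
    return ExpressionDataset(
        counts=sp.hstack([d.counts for d in datasets]).tocsr(),
        gene_ids=first.gene_ids.copy(),
        cell_ids=np.concatenate([d.cell_ids for d in datasets]),
        annotations=pd.concat([d.annotations for d in datasets], ignore_index=True),
    )


@dataclass
class GeneSet:
    """A named set of gene symbols (e.g., susceptibility, HI or LoFT genes)."""

    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        _check(len(self.genes) > 0, f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(sorted(self.genes))


@dataclass
class VariantTable:
    """Pre-annotated variants: gene symbol, variant id, consequence, allele frequency."""

    records: pd.DataFrame  # columns: gene, variant_id, consequence, af

    def __post_init__(self) -> None:
        required = ["gene", "variant_id", "consequence", "af"]
        missing = [c for c in required if c not in self.records.columns]
        _check(not missing, f"variant table missing columns: {missing}")
        af = self.records["af"].to_numpy(dtype=float)
        bad = np.flatnonzero((af < 0) | (af > 1))
        if bad.size:
            raise ValidationError(
                f"allele frequency outside [0,1] at row {bad[0]}: af={af[bad[0]]}"
            )
        self.records = self.records[required].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class InteractionSet:
    """Unordered gene pairs from a reference interaction catalogue.

    ``universe_size`` is the number of protein-coding genes spanning the
    sampling space of n(n-1)/2 possible pairs, used to form the background
    proportion for the edge-overlap binomial test.
    """

    pairs: frozenset  # of frozenset({a, b})
    universe_size: int

    def __post_init__(self) -> None:
        _check(self.universe_size >= 2, "universe_size must be >= 2")
        clean = set()
        for pair in self.pairs:
            a, b = tuple(pair)
            _check(a != b, f"self-pair not allowed: {a}")
            clean.add(frozenset((a, b)))
        self.pairs = frozenset(clean)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        a, b = tuple(pair)
        return frozenset((a, b)) in self.pairs


@dataclass
class GeneNetwork:
    """Undirected gene network with partial-correlation edges.

    Nodes carry ``mean_expression`` (mean of log1p counts in the stratum);
    edges carry ``partial_corr`` (the conditional dependence strength that
    defines the edge) and ``pearson_r`` (the marginal correlation).
    ``stratum`` records the cell selection the network was built from.
    """

    graph: "object"  # networkx.Graph
    stratum: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.graph
        for u, v, data in g.edges(data=True):
            _check(u != v, f"self-edge not allowed: {u}")
            rho = data.get("partial_corr")
            r = data.get("pearson_r")
            if rho is not None:
                _check(-1 <= rho <= 1, f"partial_corr out of range on edge ({u},{v})")
            if r is not None:
                _check(-1 - 1e-12 <= r <= 1 + 1e-12,
                       f"pearson_r out of range on edge ({u},{v})")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_pairs(self) -> set:
        return {frozenset((u, v)) for u, v in self.graph.edges()}
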