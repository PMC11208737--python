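"""Dosage strictness: the spread of per-cell expression fold change.

For a gene with expression E_i in cell i and mean expression Ebar over the
selected cells, the fold change is C_i = E_i / Ebar (so the fold changes
average to exactly 1 by construction) and strictness is

    S = 1 / sqrt( sum_i (C_i - Cbar)^2 / (n - 1) )

i.e., the reciprocal sample standard deviation of the fold change.  A high
S means the gene's dosage is tightly controlled across cells; a low S
means expression tolerates large swings.  S is invariant to rescaling the
gene's expression vector by any positive constant.

Significance of a target set's mean strictness is assessed against a
bootstrap null: equal-size gene draws (without replacement within a draw)
from the finite-strictness background, a maximum-likelihood normal fit to
the bootstrap means (the central-limit approximation), and the upper-tail
probability p = 1 - Phi((x - mu) / sigma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionDataset, GeneSet, ValidationError


@dataclass
class StrictnessTable:
    """Per-gene strictness over a cell selection.

    ``strictness`` is +inf for constant nonzero genes (zero fold-change
    spread) and NaN for genes with zero mean expression (fold change
    undefined).
    """

    table: pd.DataFrame  # index: gene; columns: strictness, mean_expression, n_cells

    def __post_init__(self) -> None:
        finite = self.table["strictness"].to_numpy()
        finite = finite[np.isfinite(finite)]
        if finite.size and finite.min() <= 0:
            raise ValidationError("strictness must be positive")

    def finite_background(self, min_mean: float = 0.0) -> pd.Series:
        """Genes with finite strictness (and mean expression > min_mean)."""
        t = self.table
        keep = np.isfinite(t["strictness"]) & (t["mean_expression"] > min_mean)
        return t.loc[keep, "strictness"]

    def values_for(self, genes: GeneSet) -> pd.Series:
        present = [g for g in genes if g in self.table.index]
        return self.table.loc[present, "strictness"]


@dataclass
class StrictnessSignificance:
    """Normal-approximation significance of a target set's mean strictness."""

    target_name: str
    n_targets: int
    observed_mean: float
    null_mean: float     # MLE mu of bootstrap means
    null_sd: float       # MLE sigma (population SD) of bootstrap means
    p: float             # 1 - Phi((x - mu) / sigma)
    n_boot: int


def compute_strictness(dataset: ExpressionDataset, cell_mask=None) -> StrictnessTable:
    """Strictness of every gene over the masked cells.

    ``cell_mask`` is a boolean mask or index array over cells (default:
    all cells); at least two cells are required.
    """
    if cell_mask is None:
        cell_mask = np.ones(dataset.n_cells, dtype=bool)
    sub = dataset.counts[:, np.flatnonzero(np.asarray(cell_mask))
                         if np.asarray(cell_mask).dtype == bool else cell_mask]
    n = sub.shape[1]
    if n < 2:
        raise ValidationError("strictness requires at least two cells")

    dense = np.asarray(sub.todense(), dtype=float)
    mean = dense.mean(axis=1)
    strictness = np.full(dataset.n_genes, np.nan)
    pos = mean > 0
    if pos.any():
        fold = dense[pos] / mean[pos, None]
        sd = fold.std(axis=1, ddof=1)
        with np.errstate(divide="ignore"):
            strictness[pos] = np.where(sd > 0, 1.0 / sd, np.inf)
    table = pd.DataFrame(
        {"strictness": strictness, "mean_expression": mean, "n_cells": n},
        index=pd.Index(dataset.gene_ids, name="gene"),
    )
    return StrictnessTable(table=table)


def compare_strictness(table: StrictnessTable, set_a: GeneSet, set_b: GeneSet,
                       alternative: str = "two-sided"):
    """Wilcoxon rank-sum comparison of strictness between two gene sets.

    Infinite sentinels (constant genes) rank above every finite value,
    which the rank-based test handles natively.  Returns (statistic, p).
    """
    a = table.values_for(set_a).dropna().to_numpy()
    b = table.values_for(set_b).dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both gene sets must overlap the strictness table")
    return _ranksum(a, b, alternative)


def _ranksum(a: np.ndarray, b: np.ndarray, alternative: str):
    """Rank-sum test; exact by full enumeration for small samples.

    For combined sample size <= 12 the permutation distribution of the
    rank-sum statistic is enumerated exhaustively (midranks for ties);
    larger samples use the Mann-Whitney U implementation.
    """
    n_a, n_b = len(a), len(b)
    pooled_all = np.concatenate([a, b])
    if np.all(pooled_all == pooled_all[0]):  # no information in ranks
        return float(stats.rankdata(pooled_all)[:n_a].sum()), 1.0
    if n_a + n_b <= 12:
        from itertools import combinations

        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)  # midranks
        obs = ranks[:n_a].sum()
        sums = np.array([sum(ranks[list(c)])
                         for c in combinations(range(n_a + n_b), n_a)])
        eps = 1e-9
        if alternative == "two-sided":
            mean = sums.mean()
            p = np.mean(np.abs(sums - mean) >= abs(obs - mean) - eps)
        elif alternative == "less":
            p = np.mean(sums <= obs + eps)
        elif alternative == "greater":
            p = np.mean(sums >= obs - eps)
        else:
            raise ValidationError(f"unknown alternative: {alternative!r}")
        return float(obs), float(p)
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def strictness_significance(
    table: StrictnessTable,
    targets: GeneSet,
    n_boot: int = 500_000,
    seed: int = 0,
    background_min_mean: float = 0.0,
) -> StrictnessSignificance:
    """Bootstrap-MLE normal significance of a target set's mean strictness.

    The background pool is every gene with finite strictness and mean
    expression above ``background_min_mean`` in the masked cells.  Each of
    the ``n_boot`` bootstrap replicates draws ``n = |targets ∩ pool|``
    genes without replacement; the normal null N(mu, sigma^2) is the MLE
    fit (sample mean; population SD) to the replicate means.
    """
    pool = table.finite_background(background_min_mean)
    target_values = table.values_for(targets)
    target_values = target_values[np.isfinite(target_values)]
    n = len(target_values)
    if n < 2:
        raise ValidationError("need at least two finite-strictness target genes")
    if len(pool) < n:
        raise ValidationError("background pool smaller than the target set")

    observed = float(target_values.mean())
    rng = np.random.default_rng(np.random.SeedSequence((seed, 505)))
    pool_values = pool.to_numpy()

    boot_means = np.empty(n_boot)
    chunk = max(1, int(1e7 // len(pool_values)))
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        keys = rng.random((stop - start, len(pool_values)))
        pick = np.argpartition(keys, n - 1, axis=1)[:, :n]
        boot_means[start:stop] = pool_values[pick].mean(axis=1)

    mu = float(boot_means.mean())
    sigma = float(boot_means.std(ddof=0))  # MLE of the normal SD
    if sigma <= 0:
        raise ValidationError("degenerate bootstrap distribution (sigma = 0)")
    p = float(stats.norm.sf(observed, loc=mu, scale=sigma))
    # clamp into the open interval so downstream -log10 etc. stay finite
    tiny = np.finfo(float).tiny
    p = min(max(p, tiny), 1 - 1e-16)
    return StrictnessSignificance(
        target_name=targets.name, n_targets=n, observed_mean=observed,
        null_mean=mu, null_sd=sigma, p=p, n_boot=n_boot,
    )
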