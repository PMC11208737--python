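"""Loss-of-function classification and cumulative allele frequency.

A variant consequence is loss-of-function (LoF) when it is one of: start
lost, stop gained, stop lost, splice acceptor/donor, frameshift.  The
cumulative allele frequency of n LoF variants with allele frequencies
AF_i below the cutoff is

    CAF = 1 - prod_i (1 - AF_i)

the probability, under independence across variants, of carrying at least
one of the alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneSet, ValidationError, VariantTable

logger = logging.getLogger(__name__)

#: canonical LoF consequence stems (the trailing "_variant" is optional)
_LOF_STEMS = frozenset({
    "start_lost", "stop_gained", "stop_lost",
    "splice_acceptor", "splice_donor", "frameshift",
})

_warned_tokens: set = set()


def classify_lof(consequence: str) -> bool:
    """True iff the consequence token is a loss-of-function class.

    Matching is case-insensitive and accepts spaces or underscores as
    separators; an optional trailing ``variant`` token is stripped, so
    both ``"stop_gained"`` and ``"splice donor variant"`` qualify.
    Unknown tokens are not LoF and are logged once per token.
    """
    if not consequence or not str(consequence).strip():
        raise ValidationError("empty consequence token")
    token = str(consequence).strip().lower().replace(" ", "_")
    stem = token[: -len("_variant")] if token.endswith("_variant") else token
    if stem in _LOF_STEMS:
        return True
    if token not in _warned_tokens:
        _warned_tokens.add(token)
        logger.debug("consequence %r not in the LoF vocabulary", consequence)
    return False


@dataclass
class CAFResult:
    """Cumulative allele frequency of LoF variants in a gene set."""

    gene_set_name: str
    aggregate_caf: float                 # pooled over all qualifying variants
    per_gene_caf: dict = field(default_factory=dict)
    n_lof_variants: int = 0
    af_cutoff: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.aggregate_caf < 1:
            raise ValidationError("CAF must lie in [0, 1)")


def _caf(afs: np.ndarray) -> float:
    """1 - prod(1 - AF_i), computed in log space for numerical stability."""
    if len(afs) == 0:
        return 0.0
    return float(-np.expm1(np.log1p(-np.asarray(afs, dtype=float)).sum()))


def cumulative_allele_frequency(
    variants: VariantTable,
    genes: GeneSet,
    af_cutoff: float = 0.05,
) -> CAFResult:
    """CAF of LoF variants with AF strictly below the cutoff, in the given genes.

    Variants with af = 0 contribute nothing to the product but are counted
    in n.  An empty qualifying selection yields CAF = 0 with a warning.
    """
    records = variants.records
    is_lof = records["consequence"].map(classify_lof)
    keep = is_lof & (records["af"] < af_cutoff) & records["gene"].isin(genes.genes)
    selected = records[keep]
    if len(selected) == 0:
        logger.warning("no qualifying LoF variants for gene set %r", genes.name)
    per_gene = {
        gene: _caf(group["af"].to_numpy())
        for gene, group in selected.groupby("gene", sort=True)
    }
    return CAFResult(
        gene_set_name=genes.name,
        aggregate_caf=_caf(selected["af"].to_numpy()),
        per_gene_caf=per_gene,
        n_lof_variants=int(len(selected)),
        af_cutoff=af_cutoff,
    )


def caf_frame(result: CAFResult) -> pd.DataFrame:
    rows = [(g, c) for g, c in sorted(result.per_gene_caf.items())]
    return pd.DataFrame(rows, columns=["gene", "caf"])
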