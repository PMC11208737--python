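"""Loss-of-function cumulative allele frequency over a gene set.

CAF = 1 - prod(1 - AF_i) over LoF variants with AF below the cutoff: the
probability (assuming independent variants) that a person carries at least
one LoF allele across the set.
"""

from strictnet import (
    GeneSet,
    classify_lof,
    cumulative_allele_frequency,
    simulate_variants,
)

genes = GeneSet("eqtl_susceptibility", frozenset(f"GENE{i:02d}" for i in range(43)))
variants = simulate_variants(genes, n_variants_per_gene=12, lof_fraction=0.25, seed=3)

n_lof = int(variants.records["consequence"].map(classify_lof).sum())
print(f"{len(variants)} simulated variants over {len(genes)} genes "
      f"({n_lof} with a LoF consequence)")

result = cumulative_allele_frequency(variants, genes, af_cutoff=0.05)
print(f"qualifying LoF variants (AF < {result.af_cutoff}): {result.n_lof_variants}")
print(f"aggregate CAF over the set: {result.aggregate_caf:.3f}")
worst = max(result.per_gene_caf, key=result.per_gene_caf.get)
print(f"highest per-gene CAF: {worst} = {result.per_gene_caf[worst]:.3f}")
print()
print("The aggregate CAF is the chance of carrying >= 1 LoF allele anywhere")
print("in the set; per-gene values show where that burden concentrates.")
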