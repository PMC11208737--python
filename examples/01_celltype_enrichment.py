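"""Cell-type enrichment of a gene set, on synthetic counts with a planted answer.

Simulates four gut cell types where 25 "susceptibility" genes are expressed
20-fold higher in monocytes, then asks which cell type's expression is
enriched for that gene set.
"""

from strictnet import (
    GeneSet,
    SimulationConfig,
    Stratum,
    bootstrap_enrichment,
    compute_specificity,
    simulate_celltype_counts,
)

config = SimulationConfig(
    n_genes=800,
    specificity_fold=20.0,       # planted effect size
    strata=[Stratum(n_cells=2000, condition="control", age_group="pediatric")],
    seed=1,
)
dataset, truth = simulate_celltype_counts(config)
targets = GeneSet("susceptibility", frozenset(truth.specific_genes["monocyte"]))

spec = compute_specificity(dataset, type_field="cell_type")
results = bootstrap_enrichment(spec, targets, n_boot=10_000, seed=1)

print(f"{'cell type':<12} {'mean specificity':>17} {'boot p':>10} {'FDR q':>10}")
for r in sorted(results, key=lambda r: r.p):
    print(f"{r.cell_type:<12} {r.observed:>17.3f} {r.p:>10.2g} {r.q:>10.2g}")
print()
print("The planted cell type (monocyte) should be the only one with q < 0.05:")
print("its mean specificity exceeds that of every random equal-size gene list,")
print("while the other types sit in the bulk of the bootstrap distribution.")
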