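# strictnet

Tools for asking how disease-susceptibility genes behave inside the cell
type that carries the disease, using single-cell RNA count data:

1. **Which cell type?** Expression-weighted cell-type enrichment: the
   specificity of gene *g* in cell type *t* is
   `s(g,t) = mean_t(g) / Σ_t' mean_t'(g)`, and a gene set's mean
   specificity in a type is compared against 10,000 random equal-size gene
   lists (bootstrap p, Benjamini–Hochberg FDR across types).
2. **How tightly is dosage controlled?** The *strictness* statistic
   `S = 1 / sd(C_i)` with per-cell fold change `C_i = E_i / Ē` — the
   reciprocal spread of expression around its mean.  Gene-set significance
   comes from a bootstrap of equal-size random sets (500,000 draws) with a
   maximum-likelihood normal fit, `p = 1 − Φ((x − μ)/σ)`; set-versus-set
   contrasts use a Wilcoxon rank-sum test.
3. **What would losing one copy cost?** Loss-of-function cumulative allele
   frequency `CAF = 1 − Π(1 − AF_i)` over LoF variants (start/stop
   lost, stop gained, splice acceptor/donor, frameshift) with AF < 0.05.
4. **Are the genes wired together — and does the wiring break?**
   Condition-stratified Gaussian graphical model networks on
   `X = log(1 + C)`: an edge joins genes whose partial correlation
   `ρ_ij = −ω_ij / √(ω_ii ω_jj)` (precision entries ω) is nonzero, with
   shot-noise-corrected covariance, neighborhood selection (or graphical
   lasso), and a rotation-based penalty.  Networks are compared by density
   `d(G) = E / (V(V−1)/2)`, degree rank-sum tests, a cell-label
   permutation test on density, central-gene calls (unnormalized
   betweenness `c(v)` with degree/score thresholds), clustering
   coefficients, hierarchical subgraph partition, and a binomial test of
   edge overlap against a reference protein–protein interaction catalogue.

A synthetic-data module generates count matrices with *planted* cell-type
markers, latent network structure (chain / hub / cluster precision
matrices, optionally "broken" in the case condition), variant tables and
interaction sets, so every stage has a parameter-recovery test.

## Worked example

`python examples/04_network_contrast.py` builds an intact control network
and a case network in which 80% of the planted connections were removed:

```
           nodes  edges  density  cluster
control        30     27    0.062    0.000
case           30      5    0.011    0.000

degree rank-sum (case < control): p = 2.54e-08
central genes in the control network (degree > 5, score > 10): ['N0001', 'N0011', 'N0021']
hierarchical subgraph sizes (control, k=3): [10, 10, 10]

edge overlap with the reference set: 27/27 at background 0.00016 -> binomial p = 5.90e-103
```

The control network recovers the three planted hubs (27 of 27 true edges,
the three hub centers called as central genes, the three 10-gene blocks
found by the partition); the broken case network keeps only 5 edges, its
density drops from 0.062 to 0.011, and the rank-sum test confirms its
degrees are stochastically smaller — the quantitative signature of a
disrupted gene network.

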