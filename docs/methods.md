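# Methods

## Scope and data model

All stages operate on an `ExpressionDataset`: a genes × cells matrix of
raw read counts with one annotation record per cell (`cell_type`,
`main_type`, `condition` ∈ {case, control}, `age_group` ∈ {fetal,
pediatric, adult}, `inflammation` ∈ {inflamed, non_inflamed, NA},
`donor`).  Gene identity is the bare, case-sensitive symbol string; no
alias resolution is attempted.  Counts travel as 1-based MatrixMarket
coordinate files with headered TSV sidecars; floats are serialized with 6
significant digits, full precision internally.

## Cell-type enrichment

Specificity of gene *g* in type *t* is the mean raw count of *g* over
cells of *t*, divided by the sum of those means over all types; rows of
expressed genes sum to 1, genes with zero total mean are flagged
unexpressed and excluded from bootstrap pools.  Specificity is computed on
raw mean counts (it is invariant to a global rescaling of cells); a
`normalize="cpm"` switch rescales cells to counts per million first for
data with strong per-cell depth differences.  The annotation column
defining "type" is a parameter (`type_field`), so enrichment can run at
subtype/state or main-type resolution.

The enrichment statistic for a target set in a type is the mean
specificity of the targets present in the matrix.  The null is built by
drawing `n_boot = 10,000` random gene lists of the same size, uniformly
and without replacement within a list, from all expressed genes — no
transcript-length or GC matching.  The upper-tail p-value uses the
add-one rule `p = (1 + #{boot ≥ obs}) / (n_boot + 1)` (ties broken by ≥),
so p is never exactly 0 and is valid at finite samples; q-values are
Benjamini–Hochberg across cell types, flagged at FDR < 0.05.

Cell-composition shifts are tested by Fisher's exact test on the 2×2
table (cells of the type vs other cells) × (case vs control).

## Strictness

For the cells selected by a mask (≥ 2 required), each gene's fold changes
are `C_i = E_i / Ē`; they average to exactly 1 by construction.
Strictness is `S = 1 / sd(C)` with the n−1 sample standard deviation.
Degenerate genes carry sentinels: `Ē = 0` → undefined (NaN), constant
nonzero expression → +∞.  Sentinels are excluded from bootstrap pools and
normal fits, which they would otherwise destroy; in rank-sum contrasts +∞
simply occupies the top ranks, which a rank test handles natively.

Significance of a target set's mean strictness: draw `n_boot = 500,000`
equal-size gene sets without replacement from the finite-strictness
background, fit a normal to the bootstrap means by maximum likelihood
(sample mean; population-SD, i.e. ddof = 0), and report
`p = 1 − Φ((x − μ)/σ)`.  At 50,000 draws the fitted (μ, σ) agree with the
500,000-draw fit within 1% on a fixed seed, so tests run at the reduced
size.  The background defaults to genes with `Ē > 0` in the masked cells
(`background_min_mean` raises the floor).  Rank-sum contrasts between two
gene sets are two-sided; for combined sample sizes ≤ 12 the permutation
distribution of the rank sum is enumerated exactly (midranks for ties),
otherwise the Mann–Whitney implementation is used.

## Loss-of-function CAF

A consequence token is LoF iff its stem (case-insensitive, spaces or
underscores, optional trailing "variant") is one of: start_lost,
stop_gained, stop_lost, splice_acceptor, splice_donor, frameshift.
`CAF = 1 − Π(1 − AF_i)` over LoF variants with AF strictly below the
cutoff (default 0.05), computed in log space
(`1 − exp(Σ log(1 − AF_i))`) for numerical stability.  Variants with
AF = 0 contribute nothing but are counted in n.  The independence
assumption across variants (no haplotype phase) is inherited from the
formula and not corrected.

## Network construction

Per stratum (any combination of condition / age group / inflammation
selectors): genes detected (count > 0) in ≥ `detection_threshold` (0.1)
of the stratum's cells are kept, counts are transformed as
`X = log(1 + C)` (natural log), and a sparse Gaussian graphical model is
fitted.  An edge is a nonzero partial correlation
`ρ_ij = −ω_ij / √(ω_ii ω_jj)` given all other genes.

**Shot-noise correction.**  `log1p` of a count equals the underlying
log-expression plus independent sampling noise, which inflates each
gene's variance.  Conditioning on a noisy neighbor no longer blocks
latent paths, so the raw correlation matrix acquires weak spurious
conditional dependencies (order ρ² × noise share; empirically ≈ 0.05–0.1
at mean counts of 5–10).  Because the noise is independent across genes
it only inflates the covariance diagonal, so both estimators work from a
corrected correlation matrix: the per-gene Poisson variance on the log1p
scale — the exact conditional variance `Var[log1p(c) | λ]` tabulated over
integer rates and evaluated at the observed count, averaged over cells —
is subtracted from the diagonal (floored at 5% of the raw variance), and
the matrix is eigenvalue-clipped back to positive definite and
re-normalized.  The correction is optional (`noise_correction=False`).

**Estimators.**  Default: neighborhood selection — a lasso regression of
each gene on the rest, run by coordinate descent directly on the
corrected correlation matrix, with the AND rule on the support (both
endpoint regressions must select the edge).  Precision entries are then
recovered by unpenalized refits on the selected neighborhoods
(`ω_jj = 1/residual variance`, `ω_ij = −β_ij ω_jj`, symmetrized).
Alternative: graphical lasso on the same corrected matrix, selected
either at the rotation penalty or by EBIC (γ = 0.5) over a 10-point
path.  For a 2-gene system the reported partial correlation equals the
(corrected) Pearson correlation, as it must with an empty conditioning
set.

**Penalty selection.**  The rotation criterion permutes each gene's cell
order independently — margins preserved, all cross-gene dependence
destroyed — and records the largest absolute off-diagonal correlation;
over `n_rotations = 20` such null data sets the maximum is the smallest
penalty at which every rotation yields an empty graph.  This targets the
family-wise null scale of the correlation matrix at the observed n and p.

**Edge floor.**  Even after the diagonal correction a residual
conditional dependence of a few hundredths survives (plug-in error of the
noise estimate, log1p curvature at small counts).  An edge therefore
additionally requires a refit partial correlation of at least
`min_partial_corr = 0.1`; dependence below that scale is not resolvable
as latent network structure at these count depths.  This is the
estimator's stated resolution limit, not a tuning knob per analysis.

Cells, not donors, are the sampling units.  Edges carry the estimated
partial correlation and the marginal Pearson r; nodes carry mean log1p
expression.  The estimate is deterministic given the seed (only the
rotation criterion consumes randomness).

## Network statistics and comparison

* Density `d(G) = E / (V(V−1)/2)`, computed as an exact rational before
  the float cast.
* Central score: unnormalized betweenness centrality, unordered
  source–target pairs counted once, disconnected pairs contributing 0.
  The ordered-pair convention would double every score; the unordered
  convention is fixed and recorded here.
* Clustering coefficient per node: triangle density
  `triangles / (d(d−1)/2)`; nodes with degree < 2 report 0 and are
  excluded from the network-level mean (the "cluster" summary).
* Central genes: strict thresholds, degree > 5 AND score > 180 by
  default, with the relaxed (4, 50) variant as a second preset.
* Degree comparison: one-sided rank-sum (case < control), with an
  optional gene universe to include isolated, degree-0 members; exact
  enumeration at combined n ≤ 12 as above.
* Density difference between two strata: a cell-label permutation test —
  stratum labels are reshuffled over the pooled cells (sizes preserved),
  both networks are rebuilt from scratch per permutation, and
  `p = (1 + #{|Δd_perm| ≥ |Δd_obs|}) / (n_perm + 1)`.  The penalty is
  fixed once from the pooled cells so permutations differ only in the
  label assignment.  The test construction is this package's own design;
  it conditions on the stratum sizes and the pooled expression.
* Subgraph partition: average-linkage hierarchical clustering on the
  distance 1 − |ρ| for connected pairs and 1 otherwise, cut at a cluster
  count or height; members of different connected components cannot merge
  below height 1.
* Edge overlap with a reference interaction catalogue: the unique
  unordered edge union across strata is scored against
  `p0 = |reference| / C(universe, 2)` by an exact one-sided binomial
  upper tail `P(X ≥ k | n_edges, p0)`.

## Synthetic data

Two generators, two estimands.

*Cell-type counts* — negative binomial (Gamma–Poisson, dispersion 2.0)
per gene and type; baseline per-gene means are lognormal(0, 1); a planted
specific gene's mean is multiplied by the fold `f` (default 20) in its
target type.  Types default to four equal proportions over 2,000 cells
per stratum.

*Network counts* — Poisson-lognormal: a latent Gaussian layer
`z ~ MVN(0, Ω⁻¹)` standardized to unit marginal variance (partial
correlations are invariant to that diagonal rescaling), then
`counts ~ Poisson(exp(log_mean + latent_scale · z))` with
`log_mean = log 10`, `latent_scale = 0.8`.  The mean count of 10 puts the
shot-noise share of the log-scale variance near 15%, low enough that the
latent partial-correlation structure — the stated estimand — is
recoverable after the correction above; these genes represent
well-expressed targets in their home cell type.  Planted precision
matrices: chain (tridiagonal), hub (stars of `hub_size` genes), cluster
(block cliques), all diagonally loaded to positive definiteness when
needed (`Ω ← Ω + (|λ_min| + 0.1) I`).  The "case" condition zeroes a
`broken_fraction` of the off-diagonal support before re-loading.

Variant tables draw allele frequencies from Beta(0.5, 30) (a
rare-variant-heavy spectrum) and plant exactly
`round(lof_fraction × n)` LoF consequences per gene; interaction sets are
the planted edges plus uniformly sampled non-edge decoys.

All randomness flows through NumPy's PCG64 via `SeedSequence`; each
stratum receives an independent spawned substream, so adding a stratum
never perturbs another, and a fixed seed reproduces output bit for bit.

What the generators do **not** emulate: doublets, ambient RNA, batch and
donor effects, zero inflation beyond the count model, realistic cell-type
catalogs, linkage between variants.  Passing recovery tests therefore
demonstrates correctness of the estimators under their own assumptions,
not robustness to those artifacts.

## Test problem sizes

Recovery and calibration tests run at: chain m = 5 (partial correlation
0.5) and hub m = 50 (0.3) with 5,000 cells; enrichment at f = 20, four
types, 2,000 cells, 1,000 bootstrap draws (10,000 remains the analysis
default); strictness at 50,000 bootstrap draws (500,000 default; the
fitted null agrees within 1%); the broken-network contrast at m = 20,
`broken_fraction = 0.8`, 1,500 cells per condition, 199 permutations.
Graph metrics are checked against exhaustive brute-force oracles on every
labeled graph with ≤ 6 nodes, and the overlap binomial against full
outcome enumeration at n ≤ 12.

## Known limitations

* The GGM assumes an approximately Gaussian latent layer; heavy
  zero-inflation or very low counts (mean ≪ 1) push `log1p` far from that
  regime and weaken both the correction and the estimators.
* Edges with latent partial correlation below the 0.1 floor are
  undetectable by design; raising counts or cells does not change the
  floor, only the reliability above it.
* The strictness normal null relies on the central limit theorem; for
  very small target sets (n < ~10) over heavy-tailed strictness
  distributions the tail p-values are approximate.
* CAF assumes independent variants; within-gene haplotype structure
  makes it an upper bound on carrier probability.
* The density permutation test conditions on pooled expression and
  stratum sizes; it does not model donor-level correlation (a
  donor-level bootstrap is out of scope).
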