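"""Condition-stratified gene networks from a Gaussian graphical model.

The pipeline per stratum is: keep genes detected in at least a fraction
``detection_threshold`` of cells, transform counts as ``X = log(1 + C)``
(natural log), then estimate a sparse precision matrix whose off-diagonal
support defines the edge set

    E = { {i, j} : rho_ij | rest != 0 },   rho_ij = -w_ij / sqrt(w_ii w_jj)

where w are precision entries.  Two standard sparse estimators are
provided: neighborhood selection (per-node lasso, AND rule on the support;
the default) and the graphical lasso.  Regularization is chosen by a
rotation criterion — the mean over random per-gene cell permutations of
the largest absolute off-diagonal correlation, i.e. the penalty at which
a dependence-free rotation of the data stays empty — or, for the
graphical lasso, by EBIC.

Count sampling noise and the GGM.  ``log1p`` of a count is the underlying
log-expression plus independent shot noise, which inflates each gene's
variance; conditioning on a noisy neighbor then no longer blocks latent
paths, so the raw correlation matrix acquires weak spurious conditional
dependencies.  Both estimators therefore work from a noise-corrected
covariance: the per-gene Poisson variance on the log1p scale (delta
method, ``mean(c / (1 + c)^2)`` over cells) is subtracted from the
covariance diagonal before standardizing and inverting, which is
consistent for the latent structure because the noise is independent
across genes.  Pass ``noise_correction=False`` (or omit the counts) to
work on the raw covariance.

Even after the diagonal correction, a residual conditional dependence of
order a few hundredths survives at typical count depths (plug-in error of
the noise estimate, log1p curvature at small counts).  Edge calling
therefore applies a floor: an edge needs both support in the penalized
estimate and a refit partial correlation of at least ``min_partial_corr``
(default 0.1), the resolution limit below which conditional dependence
cannot be attributed to the latent network rather than the measurement
layer.

Edges carry the estimated partial correlation and the marginal Pearson r;
nodes carry mean expression on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
from scipy import sparse

from .containers import ExpressionDataset, GeneNetwork, GeneSet, ValidationError


@dataclass
class GGMConfig:
    """Knobs of the network-construction stage."""

    method: str = "mb"              # "mb" (neighborhood selection) or "glasso"
    criterion: str = "ric"          # "ric" or "ebic" (glasso only)
    lambda_: float | None = None    # fixed penalty overrides the criterion
    n_rotations: int = 20
    ebic_gamma: float = 0.5
    detection_threshold: float = 0.1
    min_cells: int = 50
    genes: GeneSet | None = None    # restrict the network to this gene set
    noise_correction: bool = True   # subtract Poisson noise variance (needs counts)
    min_partial_corr: float = 0.1   # edge floor: resolution limit of the edge call


@dataclass
class PrecisionEstimate:
    """Sparse precision matrix over the filtered genes."""

    gene_ids: np.ndarray
    precision: np.ndarray
    covariance: np.ndarray
    lambda_: float
    method: str
    criterion: str

    def __post_init__(self) -> None:
        w = self.precision
        if not np.allclose(w, w.T, atol=1e-8):
            raise ValidationError("precision estimate must be symmetric")
        if np.any(np.diag(w) <= 0):
            raise ValidationError("precision diagonal must be positive")

    def partial_correlations(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.precision))
        rho = -self.precision / np.outer(d, d)
        np.fill_diagonal(rho, 1.0)
        return np.clip(rho, -1.0, 1.0)


def filter_genes(dataset: ExpressionDataset, cell_mask=None,
                 detection_threshold: float = 0.1) -> list:
    """Genes detected (count > 0) in at least the threshold fraction of cells."""
    if cell_mask is None:
        cell_mask = np.ones(dataset.n_cells, dtype=bool)
    idx = np.flatnonzero(np.asarray(cell_mask)) \
        if np.asarray(cell_mask).dtype == bool else np.asarray(cell_mask)
    if idx.size == 0:
        raise ValidationError("empty cell mask")
    sub = dataset.counts[:, idx]
    detected = np.asarray((sub > 0).sum(axis=1)).ravel() / idx.size
    return [g for g, frac in zip(dataset.gene_ids, detected)
            if frac >= detection_threshold]


def log_transform(counts) -> np.ndarray:
    """X = log(1 + C), elementwise natural log; keeps the genes x cells layout."""
    if sparse.issparse(counts):
        counts = np.asarray(counts.todense())
    counts = np.asarray(counts, dtype=float)
    if counts.size and counts.min() < 0:
        raise ValidationError("counts must be nonnegative")
    return np.log1p(counts)


def pearson_matrix(X: np.ndarray) -> np.ndarray:
    """Gene-gene Pearson correlations (genes are rows, cells columns).

    Zero-variance genes yield NaN rows/columns rather than a silent zero.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 3:
        raise ValidationError("need at least 3 cells for correlations")
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r = np.asarray(r, dtype=float)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, np.where(sd == 0, np.nan, 1.0))
    return np.clip(r, -1.0, 1.0, out=r, where=~np.isnan(r))


def rotation_lambda(Xn: np.ndarray, n_rotations: int, rng: np.random.Generator) -> float:
    """Penalty from dependence-free rotations of the data (cells x genes).

    Each rotation permutes every gene's cell order independently, which
    keeps the margins but destroys all cross-gene dependence; the returned
    penalty is the largest absolute off-diagonal correlation observed over
    the rotations — the smallest penalty at which every rotated (null)
    data set produces an empty graph.
    """
    n, p = Xn.shape
    maxima = np.empty(n_rotations)
    for k in range(n_rotations):
        Xr = np.empty_like(Xn)
        for j in range(p):
            Xr[:, j] = Xn[rng.permutation(n), j]
        c = np.corrcoef(Xr, rowvar=False)
        np.fill_diagonal(c, 0.0)
        maxima[k] = np.abs(c).max()
    return float(maxima.max())


@lru_cache(maxsize=1)
def _poisson_log1p_var_table(k_max: int = 400) -> np.ndarray:
    """Exact Var[log1p(c) | lambda = k] for integer rates k = 0..k_max."""
    from scipy import stats

    ks = np.arange(0, k_max + 300)
    f = np.log1p(ks)
    table = np.empty(k_max + 1)
    table[0] = 0.0
    for k in range(1, k_max + 1):
        pmf = stats.poisson.pmf(ks, k)
        m = float(pmf @ f)
        table[k] = float(pmf @ (f * f)) - m * m
    return table


def _shot_noise_variance(counts: np.ndarray) -> np.ndarray:
    """Per-gene Poisson sampling variance on the log1p scale.

    Plug-in estimate: the exact conditional variance v(lambda) evaluated
    at lambda = observed count, averaged over cells (delta-method tail
    ``c / (1 + c)^2`` beyond the table, where it is accurate).
    """
    table = _poisson_log1p_var_table()
    k_max = len(table) - 1
    k = np.rint(counts).astype(int)
    v = np.where(k <= k_max, table[np.clip(k, 0, k_max)],
                 counts / (1.0 + counts) ** 2)
    return v.mean(axis=1)


def corrected_correlation(X: np.ndarray, counts=None) -> np.ndarray:
    """Correlation of X with per-gene count noise removed from the diagonal.

    ``counts`` are the raw counts behind ``X = log1p(counts)``; the Poisson
    sampling variance contributed to each gene on the log1p scale
    (:func:`_shot_noise_variance`) is subtracted from the covariance
    diagonal (floored at 5% of the raw variance).  Because the sampling
    noise is independent across genes it only inflates the diagonal, so
    the corrected matrix is consistent for the latent correlation.  The
    result is eigenvalue-clipped back to positive definite and
    re-normalized to unit diagonal.  Without counts this is the ordinary
    correlation.
    """
    X = np.asarray(X, dtype=float)
    S = np.cov(X)
    if np.any(np.diag(S) <= 0):
        raise ValidationError("zero-variance gene in the network input; filter first")
    if counts is not None:
        if sparse.issparse(counts):
            counts = np.asarray(counts.todense())
        c = np.asarray(counts, dtype=float)
        noise = _shot_noise_variance(c)
        diag = np.maximum(np.diag(S) - noise, 0.05 * np.diag(S))
        S = S - np.diag(np.diag(S) - diag)
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    # PD repair: shrinking only the diagonal can push eigenvalues below zero
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < 1e-8:
        vals = np.clip(vals, 1e-8, None)
        R = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
    return R


def _cov_lasso(gram: np.ndarray, cov_xy: np.ndarray, lam: float,
               max_iter: int = 500, tol: float = 1e-8) -> np.ndarray:
    """Lasso from second moments only: coordinate descent on
    0.5 b' G b - b' c + lam ||b||_1 with unit-diagonal G."""
    p = len(cov_xy)
    beta = np.zeros(p)
    active = cov_xy.copy()  # gradient residual: c - G @ beta (excluding own term)
    for _ in range(max_iter):
        delta = 0.0
        for k in range(p):
            r = active[k] + beta[k]  # G_kk = 1
            new = np.sign(r) * max(abs(r) - lam, 0.0)
            if new != beta[k]:
                step = new - beta[k]
                active -= step * gram[:, k]
                beta[k] = new
                delta = max(delta, abs(step))
        if delta < tol:
            break
    return beta


def _mb_precision(R: np.ndarray, lam: float) -> np.ndarray:
    """Neighborhood selection on a correlation matrix, OLS refit on the
    AND-rule support.

    Per-node lasso coefficients give candidate neighborhoods; an edge is
    kept when both endpoint regressions select it.  Precision entries come
    from unpenalized refits on the selected neighborhoods:
    w_jj = 1 / residual variance, w_ij = -beta_ij * w_jj, symmetrized.
    """
    p = R.shape[0]
    selected = np.zeros((p, p), dtype=bool)
    for j in range(p):
        others = np.delete(np.arange(p), j)
        beta = _cov_lasso(R[np.ix_(others, others)], R[others, j], lam)
        selected[j, others] = beta != 0
    support = selected & selected.T  # AND rule

    omega = np.zeros((p, p))
    for j in range(p):
        nbrs = np.flatnonzero(support[j])
        if nbrs.size == 0:
            resid_var = R[j, j]
        else:
            beta = np.linalg.solve(R[np.ix_(nbrs, nbrs)], R[nbrs, j])
            resid_var = R[j, j] - R[nbrs, j] @ beta
        resid_var = max(float(resid_var), 1e-12)
        omega[j, j] = 1.0 / resid_var
        if nbrs.size:
            omega[j, nbrs] = -beta / resid_var
    omega = 0.5 * (omega + omega.T)
    omega[~support & ~np.eye(p, dtype=bool)] = 0.0
    return omega


def _ebic(emp_cov: np.ndarray, precision: np.ndarray, n: int, gamma: float) -> float:
    p = precision.shape[0]
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return np.inf
    loglik = 0.5 * n * (logdet - np.trace(emp_cov @ precision))
    n_edges = int((np.abs(precision[np.triu_indices(p, 1)]) > 1e-6).sum())
    return -2 * loglik + n_edges * np.log(n) + 4 * n_edges * gamma * np.log(p)


def _glasso_precision(R: np.ndarray, n: int, config: GGMConfig,
                      lam_ric: float | None) -> tuple[np.ndarray, float]:
    import warnings

    from sklearn.covariance import graphical_lasso

    def fit(lam):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return graphical_lasso(R, alpha=lam, max_iter=300)[1]

    if config.lambda_ is not None:
        return fit(config.lambda_), config.lambda_
    if config.criterion == "ric":
        return fit(lam_ric), lam_ric
    off = np.abs(R - np.eye(R.shape[0]))
    lam_max = max(off.max(), 1e-3)
    path = np.geomspace(lam_max, lam_max / 10, 10)
    best, best_score, best_lam = None, np.inf, None
    for lam in path:
        try:
            prec = fit(lam)
        except FloatingPointError:
            continue
        score = _ebic(R, prec, n, config.ebic_gamma)
        if score < best_score:
            best, best_score, best_lam = prec, score, lam
    if best is None:
        raise ValidationError("graphical lasso failed along the whole path")
    return best, float(best_lam)


def estimate_ggm(
    X: np.ndarray,
    gene_ids,
    config: GGMConfig | None = None,
    seed: int = 0,
    counts=None,
) -> tuple[PrecisionEstimate, GeneNetwork]:
    """Sparse GGM from a genes x cells expression matrix (already log scale).

    ``counts`` (the raw counts behind X) enables the shot-noise variance
    correction; without them the raw covariance is used.  Returns the
    precision estimate and a network whose edges are the off-diagonal
    support, annotated with partial correlations, Pearson r and node mean
    expression.  Deterministic under ``seed`` (only the rotation criterion
    consumes randomness).
    """
    config = config or GGMConfig()
    X = np.asarray(X, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    p, n = X.shape
    if p < 2:
        raise ValidationError("need at least two genes")
    if n <= 10:
        raise ValidationError("need more than 10 cells")
    if len(gene_ids) != p:
        raise ValidationError("gene_ids length must match the gene dimension")

    R = corrected_correlation(X, counts if config.noise_correction else None)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 606)))

    lam_ric = None
    if config.lambda_ is not None:
        lam = config.lambda_
    else:
        sd = X.std(axis=1)
        if np.any(sd == 0):
            raise ValidationError("zero-variance gene in the network input; filter first")
        Xs = ((X - X.mean(axis=1, keepdims=True)) / sd[:, None]).T
        lam_ric = rotation_lambda(Xs, config.n_rotations, rng)
        lam = lam_ric

    if config.method == "mb":
        omega = _mb_precision(R, lam)
    elif config.method == "glasso":
        omega, lam = _glasso_precision(R, n, config, lam_ric)
    else:
        raise ValidationError(f"unknown method: {config.method!r}")

    if config.min_partial_corr > 0:
        # edge floor: residual shot-noise bias after the diagonal correction
        # is of order a few hundredths at typical count depths; conditional
        # dependence below the floor is not resolvable as network structure
        d = np.sqrt(np.diag(omega))
        rho_all = np.abs(omega) / np.outer(d, d)
        weak = (rho_all < config.min_partial_corr) & ~np.eye(p, dtype=bool)
        omega[weak] = 0.0

    estimate = PrecisionEstimate(
        gene_ids=gene_ids, precision=omega, covariance=R,
        lambda_=float(lam), method=config.method, criterion=config.criterion,
    )

    rho = estimate.partial_correlations()
    r = pearson_matrix(X)
    g = nx.Graph()
    mean_expr = X.mean(axis=1)
    for i, gene in enumerate(gene_ids):
        g.add_node(gene, mean_expression=float(mean_expr[i]))
    for i in range(p):
        for j in range(i + 1, p):
            if abs(omega[i, j]) > 1e-10:
                g.add_edge(gene_ids[i], gene_ids[j],
                           partial_corr=float(rho[i, j]),
                           pearson_r=float(r[i, j]))
    network = GeneNetwork(graph=g, stratum={"method": config.method,
                                            "lambda": float(lam)})
    return estimate, network


def build_stratum_network(
    dataset: ExpressionDataset,
    stratum_selector: dict,
    config: GGMConfig | None = None,
    seed: int = 0,
) -> GeneNetwork:
    """Filter -> log transform -> GGM on the cells of one stratum.

    ``stratum_selector`` maps annotation fields to required values, e.g.
    ``{"condition": "case", "age_group": "pediatric"}``; ``config.genes``
    restricts the network to a target gene set (e.g. susceptibility genes).
    """
    config = config or GGMConfig()
    mask = dataset.cell_mask(**stratum_selector)
    n_cells = int(mask.sum())
    if n_cells < config.min_cells:
        raise ValidationError(
            f"stratum {stratum_selector} has {n_cells} cells; need >= {config.min_cells}"
        )
    sub = dataset.subset_cells(mask)
    net = _network_from_dataset(sub, config, seed)
    net.stratum.update(stratum_selector)
    net.stratum["n_cells"] = n_cells
    return net


def _network_from_dataset(sub: ExpressionDataset, config: GGMConfig,
                          seed: int) -> GeneNetwork:
    """filter_genes -> log_transform -> estimate_ggm on a cell subset."""
    kept = filter_genes(sub, detection_threshold=config.detection_threshold)
    if config.genes is not None:
        kept = [g for g in kept if g in config.genes.genes]
    if len(kept) < 2:
        raise ValidationError("fewer than two genes pass filtering in this stratum")
    idx = sub.gene_index(kept)
    counts = sub.counts[idx, :]
    X = log_transform(counts)
    keep = X.std(axis=1) > 0
    if keep.sum() < 2:
        raise ValidationError("fewer than two variable genes in this stratum")
    X = X[keep]
    counts = counts[np.flatnonzero(keep), :]
    gene_ids = np.asarray(kept, dtype=object)[keep]
    _, network = estimate_ggm(X, gene_ids, config=config, seed=seed, counts=counts)
    return network
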