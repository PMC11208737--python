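"""Graph statistics, hub calling, network comparison and the overlap test.

Conventions: the central score is the unnormalized betweenness centrality
with unordered source-target pairs counted once; the network-level
clustering coefficient is the mean per-node coefficient over nodes with
degree >= 2 (nodes of degree < 2 report 0 and are excluded from the mean);
graph density is E / (V (V - 1) / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import GeneNetwork, InteractionSet, ValidationError
from .ggm import GGMConfig
from .strictness import _ranksum


@dataclass
class NetworkMetrics:
    """Node, edge, density, centrality and clustering summary of one network."""

    n_nodes: int
    n_edges: int
    density: float
    degrees: dict
    central_scores: dict
    clustering: dict
    network_clustering: float  # mean cl(v) over nodes with degree >= 2
    subgraph_labels: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        nodes = sorted(self.degrees)
        return pd.DataFrame({
            "gene": nodes,
            "degree": [self.degrees[n] for n in nodes],
            "central_score": [self.central_scores[n] for n in nodes],
            "clustering": [self.clustering[n] for n in nodes],
            "subgraph": [self.subgraph_labels.get(n, 0) for n in nodes],
        })

    def summary(self) -> dict:
        return {"node": self.n_nodes, "edge": self.n_edges,
                "density": self.density, "cluster": self.network_clustering}


@dataclass
class CentralGeneCall:
    gene: str
    degree: int
    central_score: float
    degree_min: int
    score_min: float
    called: bool


@dataclass
class OverlapTest:
    """One-sided binomial test of edge overlap with a reference catalogue."""

    n_edges: int
    k_overlap: int
    background_p: float
    p: float


def graph_density(n_nodes: int, n_edges: int) -> float:
    """d(G) = E / (V (V - 1) / 2), exact rational before the float cast."""
    if n_nodes < 2:
        raise ValidationError("density requires at least two nodes")
    return float(Fraction(2 * n_edges, n_nodes * (n_nodes - 1)))


def central_scores(network: GeneNetwork | nx.Graph) -> dict:
    """Unnormalized betweenness centrality, unordered pairs counted once.

    c(v) = sum over node pairs {s,t}, both distinct from v, of the fraction
    of shortest s-t paths passing through v; disconnected pairs contribute
    nothing.
    """
    g = network.graph if isinstance(network, GeneNetwork) else network
    return {n: float(c) for n, c in
            nx.betweenness_centrality(g, normalized=False).items()}


def clustering_coefficients(network: GeneNetwork | nx.Graph) -> tuple[dict, float]:
    """Per-node triangle density and the network mean over degree >= 2 nodes.

    For an undirected simple graph the matrix form
    (A + A^T)^3_vv / (2 [d_v (d_v - 1) - 2 (A^2)_vv]) reduces to
    triangles(v) / (d_v (d_v - 1) / 2); degree < 2 nodes report 0.
    """
    g = network.graph if isinstance(network, GeneNetwork) else network
    cl = {n: float(c) for n, c in nx.clustering(g).items()}
    eligible = [cl[n] for n in g.nodes if g.degree(n) >= 2]
    network_mean = float(np.mean(eligible)) if eligible else 0.0
    return cl, network_mean


def compute_metrics(network: GeneNetwork, n_subgraphs: int | None = None) -> NetworkMetrics:
    """All per-node and network-level statistics in one pass.

    Subgraph labels come from :func:`partition_network` when
    ``n_subgraphs`` is given, otherwise from connected components.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("empty network")
    cl, network_cl = clustering_coefficients(network)
    if n_subgraphs is not None:
        labels = partition_network(network, n_clusters=n_subgraphs)
    else:
        labels = {}
        for k, comp in enumerate(nx.connected_components(g), start=1):
            for node in comp:
                labels[node] = k
    return NetworkMetrics(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        density=graph_density(g.number_of_nodes(), g.number_of_edges())
        if g.number_of_nodes() >= 2 else 0.0,
        degrees={n: int(d) for n, d in g.degree()},
        central_scores=central_scores(network),
        clustering=cl,
        network_clustering=network_cl,
        subgraph_labels=labels,
    )


def call_central_genes(metrics: NetworkMetrics, degree_min: int = 5,
                       score_min: float = 180.0) -> list[CentralGeneCall]:
    """Hub calls with strict thresholds: degree > degree_min AND score > score_min."""
    calls = []
    for gene in sorted(metrics.degrees):
        degree = metrics.degrees[gene]
        score = metrics.central_scores[gene]
        calls.append(CentralGeneCall(
            gene=gene, degree=degree, central_score=score,
            degree_min=degree_min, score_min=score_min,
            called=bool(degree > degree_min and score > score_min),
        ))
    return calls


def compare_degrees(net_a: GeneNetwork, net_b: GeneNetwork,
                    alternative: str = "less",
                    universe=None) -> tuple[float, float]:
    """Rank-sum comparison of the two degree sequences.

    Default alternative "less": degrees in ``net_a`` are stochastically
    smaller than in ``net_b`` (a disrupted network against an intact one).
    ``universe`` (optional gene list) appends degree 0 for member genes
    absent from a network, so isolated genes count.
    """
    def degree_seq(net):
        seq = [d for _, d in net.graph.degree()]
        if universe is not None:
            seq += [0] * len([g for g in universe if g not in net.graph])
        return np.array(seq, dtype=float)

    a, b = degree_seq(net_a), degree_seq(net_b)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both networks must be non-empty")
    return _ranksum(a, b, alternative)


def compare_density_permutation(
    dataset,
    stratum_a: dict,
    stratum_b: dict,
    config: GGMConfig | None = None,
    n_perm: int = 199,
    seed: int = 0,
) -> dict:
    """Cell-label permutation test for the density difference of two strata.

    The observed statistic is |d(G_a) - d(G_b)|.  Each permutation
    reshuffles which cells belong to stratum a versus b (sizes preserved),
    rebuilds both networks from scratch, and recomputes the difference;
    p = (1 + #{|delta_perm| >= |delta_obs|}) / (n_perm + 1).  The penalty
    is fixed across permutations (chosen once from the pooled cells) so
    permutations differ only in the label assignment.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    config = config or GGMConfig()

    mask_a = dataset.cell_mask(**stratum_a)
    mask_b = dataset.cell_mask(**stratum_b)
    if mask_a.sum() < config.min_cells or mask_b.sum() < config.min_cells:
        raise ValidationError("both strata need at least min_cells cells")

    def density_of(sub_dataset) -> float:
        net = _network_from_cells(sub_dataset, config, seed)
        if net.n_nodes < 2:
            return 0.0
        return graph_density(net.n_nodes, net.n_edges)

    idx_a = np.flatnonzero(mask_a)
    idx_b = np.flatnonzero(mask_b)
    pooled = np.concatenate([idx_a, idx_b])

    if config.lambda_ is None:
        # one penalty for every rebuild: estimate it on the pooled cells
        from .ggm import filter_genes, log_transform, rotation_lambda
        sub = dataset.subset_cells(pooled)
        kept = filter_genes(sub, detection_threshold=config.detection_threshold)
        if config.genes is not None:
            kept = [g for g in kept if g in config.genes.genes]
        X = log_transform(sub.counts[sub.gene_index(kept), :])
        X = X[X.std(axis=1) > 0]
        Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        rng0 = np.random.default_rng(np.random.SeedSequence((seed, 707)))
        lam = rotation_lambda(Xs.T, config.n_rotations, rng0)
        config = GGMConfig(**{**config.__dict__, "lambda_": lam})

    d_a = density_of(dataset.subset_cells(idx_a))
    d_b = density_of(dataset.subset_cells(idx_b))
    observed = d_a - d_b

    rng = np.random.default_rng(np.random.SeedSequence((seed, 808)))
    n_a = len(idx_a)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        da = density_of(dataset.subset_cells(perm[:n_a]))
        db = density_of(dataset.subset_cells(perm[n_a:]))
        if abs(da - db) >= abs(observed) - 1e-15:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return {"density_a": d_a, "density_b": d_b, "observed_diff": observed,
            "p": p, "n_perm": n_perm}


def _network_from_cells(sub_dataset, config: GGMConfig, seed: int) -> GeneNetwork:
    """build_stratum_network without a selector: use all cells of the subset."""
    from .ggm import _network_from_dataset

    return _network_from_dataset(sub_dataset, config, seed)


def partition_network(network: GeneNetwork, n_clusters: int | None = None,
                      height: float | None = None) -> dict:
    """Hierarchical subgraph labels from average-linkage clustering.

    The distance between two genes is 1 - |partial correlation| when they
    share an edge and 1 otherwise, so members of different connected
    components never merge below height 1.  Cut either at ``n_clusters``
    or at ``height``.
    """
    g = network.graph
    nodes = sorted(g.nodes)
    if not nodes:
        raise ValidationError("empty network")
    if len(nodes) == 1:
        return {nodes[0]: 1}
    if n_clusters is None and height is None:
        raise ValidationError("give n_clusters or height")

    pos = {n: i for i, n in enumerate(nodes)}
    dist = np.ones((len(nodes), len(nodes)))
    np.fill_diagonal(dist, 0.0)
    for u, v, data in g.edges(data=True):
        d = 1.0 - abs(data.get("partial_corr", 0.5))
        dist[pos[u], pos[v]] = dist[pos[v], pos[u]] = d
    link = linkage(squareform(dist, checks=False), method="average")
    if n_clusters is not None:
        labels = fcluster(link, t=n_clusters, criterion="maxclust")
    else:
        labels = fcluster(link, t=height, criterion="distance")
    return {n: int(l) for n, l in zip(nodes, labels)}


def background_proportion_from_counts(n_pairs: int, universe_size: int) -> float:
    """Catalogue pairs over all C(universe, 2) possible pairs, as an exact ratio."""
    if universe_size < 2:
        raise ValidationError("universe_size must be >= 2")
    return float(Fraction(n_pairs, universe_size * (universe_size - 1) // 2))


def background_proportion(reference: InteractionSet) -> float:
    """Reference pairs over all possible pairs of the gene universe."""
    return background_proportion_from_counts(len(reference.pairs),
                                             reference.universe_size)


def overlap_test(edges, reference: InteractionSet,
                 background_p: float | None = None) -> OverlapTest:
    """Exact one-sided binomial test of edge overlap with the reference.

    ``edges`` is the unordered-unique union of network edges across strata;
    k counts those present in the reference; under the null each edge hits
    the reference with probability p0 = |reference| / C(universe, 2), and
    p = P(X >= k | n, p0).
    """
    if len(reference.pairs) == 0:
        raise ValidationError("reference interaction set is empty")
    unique_edges = {frozenset(e) for e in edges}
    n = len(unique_edges)
    k = sum(1 for e in unique_edges if e in reference)
    p0 = background_proportion(reference) if background_p is None else background_p
    if n == 0:
        return OverlapTest(n_edges=0, k_overlap=0, background_p=p0, p=1.0)
    p = float(stats.binomtest(k, n, p0, alternative="greater").pvalue)
    return OverlapTest(n_edges=n, k_overlap=k, background_p=p0, p=p)


def union_edges(networks) -> set:
    """Unordered-unique union of edge sets over several networks."""
    out: set = set()
    for net in networks:
        out |= net.edge_pairs()
    return out
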