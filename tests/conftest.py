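import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from strictnet import ExpressionDataset
from strictnet.containers import GeneNetwork


def make_dataset(counts, gene_ids=None, cell_types=None, conditions=None,
                 age_groups=None, inflammation=None):
    """Small dense-counts dataset builder for unit tests."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(n_genes)]
    cell_types = cell_types or ["typeA"] * n_cells
    conditions = conditions or ["control"] * n_cells
    age_groups = age_groups or ["adult"] * n_cells
    inflammation = inflammation or ["NA"] * n_cells
    ann = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n_cells)],
        "cell_type": cell_types,
        "main_type": ["immune"] * n_cells,
        "condition": conditions,
        "age_group": age_groups,
        "inflammation": inflammation,
        "donor": ["d0"] * n_cells,
    })
    return ExpressionDataset(counts=sp.csr_matrix(counts), gene_ids=gene_ids,
                             cell_ids=ann["cell_id"].to_numpy(dtype=object),
                             annotations=ann)


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 cells, two cell types."""
    return make_dataset(
        [[2, 2, 0, 0],
         [1, 1, 1, 1],
         [0, 0, 3, 3]],
        cell_types=["typeA", "typeA", "typeB", "typeB"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


# --- shared graph helpers and independent oracles ---------------------------

def as_network(graph, rho=0.5):
    """Wrap a bare networkx graph as a GeneNetwork with uniform edge weights."""
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for u, v in graph.edges:
        g.add_edge(u, v, partial_corr=rho, pearson_r=rho)
    return GeneNetwork(graph=g)


def bfs_paths(adj, source, n):
    """Distances and shortest-path counts from one source (BFS layering DP)."""
    dist = [None] * n
    sigma = [0] * n
    dist[source], sigma[source] = 0, 1
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if dist[w] is None:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        frontier = nxt
    return dist, sigma


def brute_betweenness(adj, n):
    """c(v) over unordered pairs via sigma(s,v) * sigma(v,t) path counting."""
    dist, sigma = zip(*(bfs_paths(adj, s, n) for s in range(n)))
    score = [0.0] * n
    for s, t in itertools.combinations(range(n), 2):
        if dist[s][t] is None:
            continue
        for v in range(n):
            if v in (s, t) or dist[s][v] is None or dist[v][t] is None:
                continue
            if dist[s][v] + dist[v][t] == dist[s][t]:
                score[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    return score


def brute_clustering(adj, n):
    """Triangle density around each node by direct neighbor-pair counting."""
    out = []
    for v in range(n):
        nbrs = sorted(adj[v])
        d = len(nbrs)
        if d < 2:
            out.append(0.0)
            continue
        triangles = sum(1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a])
        out.append(triangles / (d * (d - 1) / 2))
    return out


def all_graphs(n):
    """Every labeled simple graph on n nodes, as adjacency sets."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in range(2 ** len(pairs)):
        adj = [set() for _ in range(n)]
        for i, (a, b) in enumerate(pairs):
            if bits >> i & 1:
                adj[a].add(b)
                adj[b].add(a)
        yield adj


def graph_from_adj(adj):
    g = nx.Graph()
    g.add_nodes_from(range(len(adj)))
    for a in range(len(adj)):
        for b in adj[a]:
            if b > a:
                g.add_edge(a, b)
    return g
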