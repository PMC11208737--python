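"""Readers and writers for every external file format the pipeline touches.

Counts travel as MatrixMarket coordinate files (1-based, per the standard)
with headered, tab-delimited sidecar TSVs for genes and cells.  Gene sets
are plain text, one symbol per line with ``#`` comments.  Variants and
reference interactions are TSVs.  Networks are written as edge-list TSV or
GraphML.

Every reader validates hard: a dimension mismatch, duplicate id, negative
count or out-of-range allele frequency raises :class:`ValidationError`
naming the offending file (and line where meaningful) rather than silently
coercing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    ANNOTATION_COLUMNS,
    ExpressionDataset,
    GeneNetwork,
    GeneSet,
    InteractionSet,
    ValidationError,
    VariantTable,
)

logger = logging.getLogger(__name__)

#: significant digits used when serializing floats
FLOAT_FORMAT = "%.6g"


def read_expression(matrix_path, genes_path, cells_path) -> ExpressionDataset:
    """Read a MatrixMarket counts file plus gene/cell TSV sidecars.

    The genes sidecar must have a ``gene_id`` column; the cells sidecar must
    carry all of :data:`~strictnet.containers.ANNOTATION_COLUMNS`.
    """
    matrix_path, genes_path, cells_path = map(Path, (matrix_path, genes_path, cells_path))
    try:
        counts = scipy.io.mmread(matrix_path)
    except Exception as exc:  # malformed MTX
        raise ValidationError(f"{matrix_path}: cannot parse MatrixMarket file: {exc}") from exc
    counts = sp.csr_matrix(counts)
    if counts.nnz and counts.data.min() < 0:
        raise ValidationError(f"{matrix_path}: negative counts present")
    if counts.nnz and not np.allclose(counts.data, np.round(counts.data)):
        raise ValidationError(f"{matrix_path}: non-integer counts present")
    counts = counts.astype(np.int64)

    genes = pd.read_csv(genes_path, sep="\t", dtype=str, keep_default_na=False)
    if "gene_id" not in genes.columns:
        raise ValidationError(f"{genes_path}: missing required column 'gene_id'")
    gene_ids = genes["gene_id"].to_numpy(dtype=object)
    dup = genes["gene_id"][genes["gene_id"].duplicated()]
    if len(dup):
        line = int(dup.index[0]) + 2  # +1 header, +1 one-based
        raise ValidationError(f"{genes_path}:{line}: duplicate gene id {dup.iloc[0]!r}")
    if len(gene_ids) != counts.shape[0]:
        raise ValidationError(
            f"{genes_path}: {len(gene_ids)} genes but {matrix_path} header declares "
            f"{counts.shape[0]} rows"
        )

    cells = pd.read_csv(cells_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in cells.columns]
    if missing:
        raise ValidationError(f"{cells_path}: missing columns {missing}")
    if len(cells) != counts.shape[1]:
        raise ValidationError(
            f"{cells_path}: {len(cells)} cells but {matrix_path} header declares "
            f"{counts.shape[1]} columns"
        )
    try:
        return ExpressionDataset(
            counts=counts,
            gene_ids=gene_ids,
            cell_ids=cells["cell_id"].to_numpy(dtype=object),
            annotations=cells,
        )
    except ValidationError as exc:
        raise ValidationError(f"{cells_path}: {exc}") from exc


def write_expression(dataset: ExpressionDataset, out_prefix) -> dict:
    """Write ``<prefix>.mtx``, ``<prefix>.genes.tsv`` and ``<prefix>.cells.tsv``.

    Returns the three paths; :func:`read_expression` reconstructs the
    dataset exactly.
    """
    dataset.validate()
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_prefix.with_suffix(".mtx"),
        "genes": Path(str(out_prefix) + ".genes.tsv"),
        "cells": Path(str(out_prefix) + ".cells.tsv"),
    }
    scipy.io.mmwrite(paths["matrix"], dataset.counts.tocoo(), field="integer")
    pd.DataFrame({"gene_id": dataset.gene_ids}).to_csv(paths["genes"], sep="\t", index=False)
    dataset.annotations[list(ANNOTATION_COLUMNS)].to_csv(paths["cells"], sep="\t", index=False)
    return paths


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Read one gene symbol per line; ``#`` starts a comment; duplicates warn."""
    path = Path(path)
    symbols: list[str] = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            token = raw.split("#", 1)[0].strip()
            if not token:
                continue
            if token in seen:
                logger.warning("%s:%d: duplicate gene symbol %r ignored", path, lineno, token)
                continue
            seen.add(token)
            symbols.append(token)
    if not symbols:
        raise ValidationError(f"{path}: gene set file is empty")
    return GeneSet(name=name or path.stem, genes=frozenset(symbols))


def write_gene_set(gene_set: GeneSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# gene set: {gene_set.name} ({len(gene_set)} genes)\n")
        for gene in gene_set:
            fh.write(gene + "\n")
    return path


def read_variant_table(path) -> VariantTable:
    """Read a TSV with header ``gene, variant_id, consequence, af``."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    required = ["gene", "variant_id", "consequence", "af"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    af = pd.to_numeric(table["af"], errors="coerce")
    bad = np.flatnonzero(af.isna() | (af < 0) | (af > 1))
    if bad.size:
        line = int(bad[0]) + 2
        raise ValidationError(
            f"{path}:{line}: allele frequency {table['af'].iloc[bad[0]]!r} outside [0,1]"
        )
    table = table.assign(af=af.astype(float))
    return VariantTable(records=table)


def write_variant_table(variants: VariantTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    variants.records.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def read_interactions(path, universe_size: int) -> InteractionSet:
    """Read a two-column TSV of gene symbols into unordered-unique pairs.

    Self-pairs are dropped with a warning; (A,B) and (B,A) collapse to one
    pair.  ``universe_size`` is the protein-coding gene count defining the
    pair sampling space.
    """
    path = Path(path)
    pairs = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not all(f.strip() for f in fields):
                raise ValidationError(f"{path}:{lineno}: expected two tab-separated symbols")
            a, b = (f.strip() for f in fields)
            if a == b:
                logger.warning("%s:%d: self-pair %r dropped", path, lineno, a)
                continue
            pairs.add(frozenset((a, b)))
    return InteractionSet(pairs=frozenset(pairs), universe_size=universe_size)


def write_interactions(interactions: InteractionSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for pair in sorted(tuple(sorted(p)) for p in interactions.pairs):
            fh.write(f"{pair[0]}\t{pair[1]}\n")
    return path


def write_network(network: GeneNetwork, path, format: str = "edge_tsv") -> Path:
    """Write a network as an edge-list TSV or GraphML file.

    The edge TSV carries partial correlation and Pearson r per edge; a
    companion ``<path>.nodes.tsv`` carries per-node mean expression.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = network.graph
    if format == "edge_tsv":
        rows = [
            {
                "gene_a": u,
                "gene_b": v,
                "partial_corr": data.get("partial_corr", np.nan),
                "pearson_r": data.get("pearson_r", np.nan),
            }
            for u, v, data in g.edges(data=True)
        ]
        edge_df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "partial_corr", "pearson_r"])
        edge_df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        node_rows = [
            {"gene": n, "mean_expression": data.get("mean_expression", np.nan)}
            for n, data in g.nodes(data=True)
        ]
        node_df = pd.DataFrame(node_rows, columns=["gene", "mean_expression"])
        node_df.to_csv(Path(str(path) + ".nodes.tsv"), sep="\t", index=False,
                       float_format=FLOAT_FORMAT)
    elif format == "graphml":
        annotated = g.copy()
        for key, value in network.stratum.items():
            annotated.graph[key] = str(value)
        nx.write_graphml(annotated, path)
    else:
        raise ValidationError(f"unknown network format: {format!r}")
    return path


def read_network(path, format: str = "edge_tsv") -> GeneNetwork:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    if format == "edge_tsv":
        edge_df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        nodes_path = Path(str(path) + ".nodes.tsv")
        if nodes_path.exists():
            node_df = pd.read_csv(nodes_path, sep="\t")
            for _, row in node_df.iterrows():
                g.add_node(row["gene"], mean_expression=float(row["mean_expression"]))
        for _, row in edge_df.iterrows():
            g.add_edge(row["gene_a"], row["gene_b"],
                       partial_corr=float(row["partial_corr"]),
                       pearson_r=float(row["pearson_r"]))
        return GeneNetwork(graph=g)
    elif format == "graphml":
        g = nx.read_graphml(path)
        return GeneNetwork(graph=nx.Graph(g), stratum=dict(g.graph))
    raise ValidationError(f"unknown network format: {format!r}")
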