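"""Readers and writers for the pipeline's TSV and GraphML formats.

Formats:

* expression matrix — TSV, header row required, first column the gene
  identifier, remaining columns ordered time points;
* candidate edges — two-column TSV ``source<TAB>target`` (directed), no
  header;
* weighted network — TSV with columns source, target, chosen_lag, te,
  robust_distance, empirical_p (``te`` doubles as the edge weight); weights
  round-trip at full precision.  GraphML export/import is also supported.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "read_edges",
    "write_edges",
    "write_network",
    "read_network",
    "write_graphml",
    "read_graphml",
]

_NETWORK_COLUMNS = ["source", "target", "chosen_lag", "te", "robust_distance", "empirical_p"]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene x time expression matrix from TSV.

    Validates: header present, at least one gene row, unique gene
    identifiers, fully numeric body with no missing cells.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no gene rows found (header-only file?)")
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicated gene identifiers: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        gene = bad.any(axis=1).idxmax()
        col = bad.loc[gene].idxmax()
        raise ValueError(f"{path}: non-numeric value at gene {gene!r}, column {col!r}")
    if numeric.isna().to_numpy().any():
        gene = numeric.isna().any(axis=1).idxmax()
        col = numeric.loc[gene].isna().idxmax()
        raise ValueError(f"{path}: missing value at gene {gene!r}, column {col!r}")
    numeric.index = numeric.index.astype(str)
    numeric.index.name = "gene"
    return numeric


def read_edges(path: str | Path) -> List[Tuple[str, str]]:
    """Read a directed candidate-edge list (two-column TSV, no header)."""
    path = Path(path)
    edges: List[Tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated columns, got {line!r}"
                )
            edges.append((parts[0], parts[1]))
    return edges


def write_edges(edges: List[Tuple[str, str]], path: str | Path) -> None:
    """Write a candidate-edge list as two-column TSV."""
    with open(path, "w") as fh:
        for src, tgt in edges:
            fh.write(f"{src}\t{tgt}\n")


def write_network(graph: nx.DiGraph, path: str | Path) -> None:
    """Write a weighted network as TSV (full float precision via repr)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_NETWORK_COLUMNS) + "\n")
        for u, v, d in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            te = d.get("weight", 1.0)
            fh.write(
                f"{u}\t{v}\t{d.get('lag', 0)}\t{te!r}\t"
                f"{d.get('robust_distance', float('nan'))!r}\t"
                f"{d.get('empirical_p', float('nan'))!r}\n"
            )


def read_network(path: str | Path) -> nx.DiGraph:
    """Read a weighted network TSV back into a digraph (lossless round-trip)."""
    path = Path(path)
    g = nx.DiGraph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _NETWORK_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_NETWORK_COLUMNS):
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            src, tgt, lag, te, dist, p = parts
            g.add_edge(
                src,
                tgt,
                weight=float(te),
                lag=int(lag),
                robust_distance=float(dist),
                empirical_p=float(p),
            )
    return g


def write_graphml(graph: nx.DiGraph, path: str | Path) -> None:
    """Export a network as GraphML."""
    nx.write_graphml(graph, str(path))


def read_graphml(path: str | Path) -> nx.DiGraph:
    """Import a GraphML network as a digraph."""
    g = nx.read_graphml(str(path))
    if not g.is_directed():
        g = g.to_directed()
    return nx.DiGraph(g)
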