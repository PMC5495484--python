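"""Topology comparisons between influence rankings and standard centralities.

The influence ranking is contrasted with classical node-centrality measures
three ways: top-k set extraction per measure, pairwise Jaccard overlap of the
top sets, and directed reachability fractions between sets (what proportion
of one top set can be reached by directed paths from another, after removing
the sets' overlap).  The centrality algorithms themselves are delegated to
networkx; this module owns the aggregation and the set comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Hashable, Iterable, List, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_METRICS",
    "centrality_table",
    "top_k_set",
    "jaccard",
    "reachable_fraction",
    "jaccard_matrix",
    "reachability_matrix",
    "ReachabilityResult",
]

#: Metrics whose "top set" is defined by a binary flag rather than top-k.
BINARY_METRICS = {"articulation"}


def _strength(g: nx.DiGraph) -> Dict[Hashable, float]:
    # summed incident edge weight, outgoing plus incoming
    out_w = g.out_degree(weight="weight")
    in_w = g.in_degree(weight="weight")
    return {v: out_w[v] + in_w[v] for v in g.nodes}


def _distance_view(g: nx.DiGraph) -> nx.DiGraph:
    # shortest-path metrics read weights as distances; strong edges (high
    # information transfer) should be short, hence distance = 1/weight
    h = g.copy()
    for u, v, w in h.edges(data="weight", default=1.0):
        h[u][v]["distance"] = 1.0 / w
    return h


def _betweenness(g: nx.DiGraph) -> Dict[Hashable, float]:
    return nx.betweenness_centrality(_distance_view(g), weight="distance")


def _closeness(g: nx.DiGraph) -> Dict[Hashable, float]:
    return nx.closeness_centrality(_distance_view(g), distance="distance")


def _alpha(g: nx.DiGraph) -> Dict[Hashable, float]:
    # Katz/alpha centrality: x = a A' x + 1, with a safely below 1/lambda_max
    A = nx.to_numpy_array(g, weight="weight")
    lam = np.max(np.abs(np.linalg.eigvals(A))) if g.number_of_edges() else 0.0
    a = 0.85 / lam if lam > 0 else 0.1
    return nx.katz_centrality_numpy(g, alpha=a, weight="weight")


def _eigenvector(g: nx.DiGraph) -> Dict[Hashable, float]:
    # leading eigenvector of A' (incoming-based importance); computed
    # directly so that disconnected graphs do not error out
    nodes = list(g.nodes)
    A = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    vals, vecs = np.linalg.eig(A.T)
    lead = int(np.argmax(np.abs(vals)))
    v = np.abs(np.real(vecs[:, lead]))
    total = v.sum()
    if total > 0:
        v = v / total
    return dict(zip(nodes, v))


def _hits(g: nx.DiGraph):
    # HITS via dense symmetric eigendecompositions (A'A for authorities,
    # AA' for hubs): deterministic, unlike ARPACK with a random start
    nodes = list(g.nodes)
    A = nx.to_numpy_array(g, nodelist=nodes, weight="weight")

    def _leading(M: np.ndarray) -> np.ndarray:
        vals, vecs = np.linalg.eigh(M)
        v = np.abs(vecs[:, -1])
        total = v.sum()
        return v / total if total > 0 else v

    hubs = dict(zip(nodes, _leading(A @ A.T)))
    auths = dict(zip(nodes, _leading(A.T @ A)))
    return hubs, auths


def _ego2(g: nx.DiGraph) -> Dict[Hashable, float]:
    # size of the 2-step out-neighborhood, the node itself included
    return {
        v: float(len(nx.single_source_shortest_path_length(g, v, cutoff=2)))
        for v in g.nodes
    }


def _subgraph(g: nx.DiGraph) -> Dict[Hashable, float]:
    return nx.subgraph_centrality(nx.Graph(g.to_undirected()))


def _inv_constraint(g: nx.DiGraph) -> Dict[Hashable, float]:
    con = nx.constraint(nx.Graph(g.to_undirected()), weight="weight")
    return {v: (1.0 - c if np.isfinite(c) else 0.0) for v, c in con.items()}


def _articulation(g: nx.DiGraph) -> Dict[Hashable, float]:
    points = set(nx.articulation_points(nx.Graph(g.to_undirected())))
    return {v: float(v in points) for v in g.nodes}


def _metric_functions():
    return {
        "degree": lambda g: {v: float(d) for v, d in g.degree()},
        "strength": _strength,
        "betweenness": _betweenness,
        "alpha": _alpha,
        "eigenvector": _eigenvector,
        "authority": lambda g: _hits(g)[1],
        "hub": lambda g: _hits(g)[0],
        "ego2": _ego2,
        "subgraph": _subgraph,
        "inv_constraint": _inv_constraint,
        "pagerank": lambda g: nx.pagerank(g, weight="weight"),
        "closeness": _closeness,
        "articulation": _articulation,
    }


DEFAULT_METRICS: List[str] = list(_metric_functions())


def centrality_table(
    graph: nx.DiGraph, metrics: Sequence[str] | None = None
) -> pd.DataFrame:
    """Compute a node-by-metric table of centrality values.

    Weighted variants use edge weights wherever the metric supports them
    (shortest-path metrics read 1/weight as distance).  Unknown metric names
    raise an error listing the supported inventory.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    funcs = _metric_functions()
    if metrics is None:
        metrics = DEFAULT_METRICS
    unknown = [m for m in metrics if m not in funcs]
    if unknown:
        raise ValueError(
            f"unknown metrics {unknown}; supported: {sorted(funcs)}"
        )
    table = pd.DataFrame(index=sorted(graph.nodes, key=str))
    for m in metrics:
        values = funcs[m](graph)
        table[m] = pd.Series(values)
    table.index.name = "node"
    return table


def top_k_set(table: pd.DataFrame, metric: str, k: int = 24) -> Set[Hashable]:
    """Top-k node set for a metric (ties broken by node identifier).

    Binary metrics (articulation) ignore ``k`` and return every flagged
    node.
    """
    if metric not in table.columns:
        raise ValueError(f"metric {metric!r} not in table")
    col = table[metric]
    if metric in BINARY_METRICS:
        return set(col[col > 0].index)
    if k < 0:
        raise ValueError("k must be nonnegative")
    k = min(k, len(col))
    order = sorted(col.items(), key=lambda item: (-item[1], str(item[0])))
    return {node for node, _ in order[:k]}


def jaccard(a: Iterable[Hashable], b: Iterable[Hashable]) -> float:
    """Jaccard index |A n B| / |A u B|; defined as 0 for two empty sets."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass(frozen=True)
class ReachabilityResult:
    """Directed reachability of one node set from another, overlap removed."""

    origin: frozenset
    targets: frozenset
    n_reached: int
    n_targets: int

    @property
    def fraction(self) -> float | None:
        """Fraction reached, or None when no targets remain after overlap
        removal."""
        if self.n_targets == 0:
            return None
        return self.n_reached / self.n_targets


def reachable_fraction(
    graph: nx.DiGraph,
    origin: Iterable[Hashable],
    targets: Iterable[Hashable],
) -> ReachabilityResult:
    """Fraction of target nodes reachable by directed paths from the origin.

    Nodes in both sets are removed from both sides before counting; a target
    is reached if any origin node has a directed path to it.
    """
    origin, targets = set(origin), set(targets)
    stray = (origin | targets) - set(graph.nodes)
    if stray:
        raise KeyError(f"nodes not in graph: {sorted(map(str, stray))}")
    overlap = origin & targets
    o = origin - overlap
    t = targets - overlap
    reached: Set[Hashable] = set()
    for v in o:
        reached |= nx.descendants(graph, v)
    return ReachabilityResult(
        origin=frozenset(o),
        targets=frozenset(t),
        n_reached=len(t & reached),
        n_targets=len(t),
    )


def jaccard_matrix(sets: Dict[str, Set[Hashable]]) -> pd.DataFrame:
    """Pairwise Jaccard matrix over named top-k sets."""
    names = list(sets)
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            mat.loc[a, b] = jaccard(sets[a], sets[b])
    return mat


def reachability_matrix(
    graph: nx.DiGraph, sets: Dict[str, Set[Hashable]]
) -> pd.DataFrame:
    """Directed reachability fractions between all ordered pairs of sets.

    Entry (row o, column t) is the fraction of set t reachable from set o
    after overlap removal; NaN when nothing remains to reach.
    """
    names = list(sets)
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for o in names:
        for t in names:
            res = reachable_fraction(graph, sets[o], sets[t])
            mat.loc[o, t] = np.nan if res.fraction is None else res.fraction
    return mat
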