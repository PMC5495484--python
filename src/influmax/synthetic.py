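"""Synthetic inputs with the statistical structure the pipeline assumes.

Real inputs to this pipeline are a time-course expression matrix (tens of
uniformly spaced measurements per gene) and a directed candidate-edge list.
These generators emulate both: expression matrices with planted lagged
regulator->target couplings amid independent-noise genes (optionally with a
shared damped cell-cycle-like wave), random weighted digraphs, and layered
"planted influencer" graphs whose optimal source sets are known by
construction.  Every generator is a pure function of its RNG seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PlantedEdge",
    "PlantedGraphSpec",
    "simulate_lagged_expression",
    "random_weighted_digraph",
    "planted_influencer_graph",
]


@dataclass(frozen=True)
class PlantedEdge:
    """A ground-truth lagged coupling: target_t = coupling * f(source_{t-lag})."""

    source: str
    target: str
    lag: int = 3
    coupling: float = 0.9
    form: str = "linear"  # or "saturating" (tanh)

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("causal couplings need lag >= 1")
        if self.coupling == 0:
            raise ValueError("coupling must be nonzero")
        if self.form not in ("linear", "saturating"):
            raise ValueError("form must be 'linear' or 'saturating'")


def simulate_lagged_expression(
    planted: Sequence[PlantedEdge],
    n_genes: int,
    n_timepoints: int = 41,
    noise_sd: float = 0.1,
    rng: np.random.Generator | int = 0,
    wave_amplitude: float = 0.0,
    wave_period: float = 14.0,
    wave_decay: float = 40.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a gene x time expression matrix with planted lagged couplings.

    Unregulated genes are independent standard Gaussian series; each planted
    target is ``coupling * f(source shifted by lag) + N(0, noise_sd^2)``
    (the initial ``lag`` points of the target are independent noise at unit
    scale).  With ``wave_amplitude > 0`` a shared damped sinusoid — a crude
    stand-in for decaying cell-cycle synchrony — is added to every gene.

    Gene identifiers are ``g000, g001, ...``; sources referenced by planted
    edges must exist among them.  Returns the expression matrix (genes in
    the index, time points ``t00..`` in the columns) and a truth table with
    columns source/target/lag/coupling.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    gene_set = set(genes)
    for e in planted:
        if e.source not in gene_set or e.target not in gene_set:
            raise ValueError(f"planted edge {e.source}->{e.target} references unknown gene")
        if e.lag >= n_timepoints / 2:
            raise ValueError(f"lag {e.lag} too large for {n_timepoints} time points")
    targets = {e.target for e in planted}
    if len(targets) < len(planted):
        raise ValueError("each gene may be the target of at most one planted edge")

    data = {g: rng.normal(0.0, 1.0, n_timepoints) for g in genes}
    # regulated genes: deterministic function of the (already generated)
    # regulator plus observation noise
    for e in planted:
        x = data[e.source]
        f = np.tanh if e.form == "saturating" else (lambda v: v)
        y = rng.normal(0.0, 1.0, n_timepoints)  # pre-regulation filler
        y[e.lag:] = e.coupling * f(x[: n_timepoints - e.lag])
        y += rng.normal(0.0, noise_sd, n_timepoints) if noise_sd > 0 else 0.0
        data[e.target] = y
    if wave_amplitude > 0:
        t = np.arange(n_timepoints, dtype=float)
        wave = wave_amplitude * np.exp(-t / wave_decay) * np.sin(2 * np.pi * t / wave_period)
        for g in genes:
            data[g] = data[g] + wave

    expr = pd.DataFrame(
        [data[g] for g in genes],
        index=pd.Index(genes, name="gene"),
        columns=[f"t{j:02d}" for j in range(n_timepoints)],
    )
    truth = pd.DataFrame(
        [
            {"source": e.source, "target": e.target, "lag": e.lag, "coupling": e.coupling}
            for e in planted
        ],
        columns=["source", "target", "lag", "coupling"],
    )
    return expr, truth


def random_weighted_digraph(
    n: int,
    m: int,
    rng: np.random.Generator | int = 0,
    weight_low: float = 0.5,
    weight_high: float = 1.5,
    n_regulators: int | None = None,
) -> nx.DiGraph:
    """Random directed graph: m distinct edges, no self-loops, U(low, high) weights.

    With ``n_regulators`` set, outgoing edges are restricted to the first
    ``n_regulators`` node ids, mimicking regulatory networks where only a
    small transcription-factor subset has out-edges and most genes are pure
    targets (sinks).  Such graphs always leak walk mass into dead ends, so
    absorbing-walk quantities stay finite.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_reg = n if n_regulators is None else int(n_regulators)
    if not (1 <= n_reg <= n):
        raise ValueError("n_regulators must be in 1..n")
    if m > n_reg * (n - 1):
        raise ValueError(
            f"m={m} exceeds the {n_reg * (n - 1)} possible directed edges"
        )
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    if m:
        # sample m distinct ordered pairs by index into the off-diagonal cells
        cells = rng.choice(n_reg * (n - 1), size=m, replace=False)
        weights = rng.uniform(weight_low, weight_high, size=m)
        for cell, w in zip(cells, weights):
            u, rem = divmod(int(cell), n - 1)
            v = rem if rem < u else rem + 1
            g.add_edge(u, v, weight=float(w))
    return g


@dataclass(frozen=True)
class PlantedGraphSpec:
    """Layered influencer test bed: roots feeding disjoint trees plus decoys."""

    n_influencers: int = 3
    depth: int = 2
    branching: int = 3
    n_decoys: int = 5
    decoy_weight: float = 1e-6
    weight_low: float = 1.0
    weight_high: float = 2.0
    seed: int = 0


def planted_influencer_graph(
    spec: PlantedGraphSpec,
) -> Tuple[nx.DiGraph, List[str]]:
    """Build a graph whose K = n_influencers optimum is the set of tree roots.

    Each root feeds a disjoint out-tree of the given depth and branching
    factor with strong edge weights, so picking all roots covers every tree
    node.  Decoy edges with negligible weight run between internal nodes of
    different trees; they add candidate edges without changing which source
    set is optimal (their transition probability, and hence visit mass, is
    far below the cover threshold).  Returns the graph and the list of root
    identifiers.
    """
    rng = np.random.default_rng(spec.seed)
    g = nx.DiGraph()
    roots: List[str] = []
    internal: List[List[str]] = []  # per tree: nodes with outgoing tree edges
    for r in range(spec.n_influencers):
        root = f"r{r}"
        roots.append(root)
        g.add_node(root)
        frontier = [root]
        tree_internal = []
        counter = 0
        for _level in range(spec.depth):
            nxt = []
            for parent in frontier:
                tree_internal.append(parent)
                for _ in range(spec.branching):
                    child = f"t{r}n{counter}"
                    counter += 1
                    w = float(rng.uniform(spec.weight_low, spec.weight_high))
                    g.add_edge(parent, child, weight=w)
                    nxt.append(child)
            frontier = nxt
        internal.append(tree_internal)

    if spec.n_decoys and spec.n_influencers > 1:
        all_nodes = list(g.nodes)
        for _ in range(spec.n_decoys):
            for _attempt in range(100):
                tree_i = int(rng.integers(spec.n_influencers))
                src = internal[tree_i][int(rng.integers(len(internal[tree_i])))]
                dst = all_nodes[int(rng.integers(len(all_nodes)))]
                if dst == src or dst in roots or g.has_edge(src, dst):
                    continue
                if dst.startswith(f"t{tree_i}n"):
                    continue  # keep decoys between different trees
                g.add_edge(src, dst, weight=spec.decoy_weight)
                break
    return g, roots
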