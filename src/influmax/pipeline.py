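"""End-to-end pipeline: infer -> score/optimize -> rank -> compare.

Each stage logs its seed and timing; all outputs are reproducible from the
configuration plus the master seed (per-stage RNG streams are spawned from
it, so stages stay independent of one another's consumption of randomness).
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Dict, Iterable, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from . import io as iomod
from .aco import rank_influence
from .config import PipelineConfig
from .network import build_te_network
from .topology import (
    DEFAULT_METRICS,
    centrality_table,
    jaccard_matrix,
    reachability_matrix,
    top_k_set,
)

__all__ = ["run_pipeline", "compare_centralities"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _timed(stage: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", stage, dt)
                return False
            logger.error("stage %s: failed after %.2fs: %s", stage, dt, exc)
            raise StageError(stage, exc) from exc

    return _Ctx()


def compare_centralities(
    graph: nx.DiGraph,
    ranking: pd.DataFrame,
    top_k: int = 24,
    metrics: Iterable[str] = DEFAULT_METRICS,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Compare the influence ranking against standard centrality measures.

    Returns (centrality table, Jaccard matrix, reachability matrix).  The
    influence top set (nodes with the highest selection counts, up to
    ``top_k`` with nonzero count) joins the per-metric top-k sets under the
    name ``influence``.
    """
    table = centrality_table(graph, list(metrics))
    selected = ranking[ranking["count"] > 0].head(top_k)
    sets: Dict[str, set] = {"influence": set(selected["node"])}
    for m in metrics:
        sets[m] = top_k_set(table, m, top_k)
    return table, jaccard_matrix(sets), reachability_matrix(graph, sets)


def run_pipeline(
    config: PipelineConfig,
    expression_path: str | Path | None = None,
    edges_path: str | Path | None = None,
    network_path: str | Path | None = None,
) -> Dict[str, Path]:
    """Run the full workflow and write all reports under ``config.outdir``.

    Either an expression matrix plus candidate edges (inference runs) or a
    pre-weighted network TSV (inference skipped) must be supplied.  Output
    files: ``network.tsv``/``network.graphml``, ``ranking.tsv``,
    ``centrality.tsv``, ``jaccard.tsv``, ``reachability.tsv``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, Path] = {}
    ss = np.random.SeedSequence(config.seed)
    infer_seed, rank_seed = ss.spawn(2)

    if network_path is None:
        if expression_path is None or edges_path is None:
            raise ValueError(
                "provide either a pre-weighted network or expression + edges"
            )
        with _timed("infer"):
            expr = iomod.read_expression(expression_path)
            candidates = iomod.read_edges(edges_path)
            logger.info(
                "infer: %d genes, %d candidate edges, n_perm=%d, seed=%d",
                len(expr), len(candidates), config.n_perm, config.seed,
            )
            graph = build_te_network(expr, candidates, config.lag_config(), infer_seed)
    else:
        with _timed("load-network"):
            graph = iomod.read_network(network_path)

    with _timed("write-network"):
        outputs["network"] = outdir / "network.tsv"
        iomod.write_network(graph, outputs["network"])
        outputs["network_graphml"] = outdir / "network.graphml"
        iomod.write_graphml(graph, outputs["network_graphml"])

    if graph.number_of_nodes() == 0:
        logger.warning("empty network: skipping optimization and comparison")
        return outputs

    k_max = min(config.k_max, graph.number_of_nodes())
    if k_max < config.k_max:
        logger.warning("k_max clipped to network size %d", k_max)
    with _timed("rank"):
        # derive a plain integer sub-seed (< 2**31) for the ranking stage
        sub_seed = int(rank_seed.generate_state(1)[0] % (2**31))
        logger.info(
            "rank: K=%d..%d reps=%d preset=%s seed=%d",
            config.k_min, k_max, config.reps, config.preset, sub_seed,
        )
        ranking = rank_influence(
            graph,
            range(config.k_min, k_max + 1),
            config.reps,
            config.aco_params(),
            seed=sub_seed,
            theta=config.theta,
        )
        outputs["ranking"] = outdir / "ranking.tsv"
        ranking.to_csv(outputs["ranking"], sep="\t", index=False)

    with _timed("compare"):
        table, jac, reach = compare_centralities(graph, ranking, config.top_k)
        outputs["centrality"] = outdir / "centrality.tsv"
        table.to_csv(outputs["centrality"], sep="\t")
        outputs["jaccard"] = outdir / "jaccard.tsv"
        jac.to_csv(outputs["jaccard"], sep="\t")
        outputs["reachability"] = outdir / "reachability.tsv"
        reach.to_csv(outputs["reachability"], sep="\t")
    return outputs
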