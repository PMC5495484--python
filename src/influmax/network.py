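"""Build statistically filtered regulatory networks from candidate edges.

Candidate regulator->target edges are tested one at a time with the lagged
transfer-entropy permutation test; accepted edges form a weighted directed
graph whose weight is the observed TE at the chosen lag.  A lagged-Spearman
alternative with Benjamini-Hochberg FDR filtering is provided for
comparison.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .entropy import EdgeTestResult, LagConfig, test_edge
from .series import lagged_spearman, lagged_spearman_abs, normalize_series

__all__ = ["build_te_network", "build_spearman_network", "bh_fdr", "results_to_frame"]

logger = logging.getLogger(__name__)

Edge = Tuple[str, str]


def _clean_candidates(
    expr: pd.DataFrame, candidates: Iterable[Edge]
) -> list[Edge]:
    """Drop self-loops and edges touching unmeasured genes (with warnings)."""
    genes = set(expr.index)
    kept: list[Edge] = []
    seen: set[Edge] = set()
    for src, tgt in candidates:
        if src == tgt:
            logger.warning("dropping self-loop %s->%s", src, tgt)
            continue
        if src not in genes or tgt not in genes:
            logger.warning(
                "skipping edge %s->%s: gene not in expression matrix", src, tgt
            )
            continue
        if (src, tgt) in seen:
            continue
        seen.add((src, tgt))
        kept.append((src, tgt))
    return kept


def build_te_network(
    expr: pd.DataFrame,
    candidates: Iterable[Edge],
    cfg: LagConfig = LagConfig(),
    seed: int | np.random.SeedSequence = 0,
) -> nx.DiGraph:
    """Test every candidate edge and keep the significant ones.

    Parameters
    ----------
    expr:
        Expression matrix, genes in the index, ordered time points in the
        columns.
    candidates:
        Directed (regulator, target) pairs.  Self-loops and pairs involving
        unmeasured genes are skipped with a logged warning.
    seed:
        Master seed; each edge draws its permutations from an independent
        spawned stream, so results do not depend on evaluation order or on
        any parallel execution strategy.

    Returns
    -------
    networkx.DiGraph whose nodes are endpoints of accepted edges; each edge
    carries ``weight`` (observed TE at the chosen lag), ``lag``,
    ``robust_distance`` and ``empirical_p`` attributes.
    """
    kept = _clean_candidates(expr, candidates)
    graph = nx.DiGraph()
    if not kept:
        return graph
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    streams = ss.spawn(len(kept))
    for (src, tgt), child in zip(kept, streams):
        res = test_edge(
            expr.loc[src].to_numpy(float),
            expr.loc[tgt].to_numpy(float),
            cfg,
            np.random.default_rng(child),
            source=src,
            target=tgt,
        )
        if res.accepted:
            graph.add_edge(
                src,
                tgt,
                weight=res.te,
                lag=res.chosen_lag,
                robust_distance=res.robust_distance,
                empirical_p=res.empirical_p,
            )
    return graph


def bh_fdr(pvalues: Sequence[float] | np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up acceptance mask at FDR level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def build_spearman_network(
    expr: pd.DataFrame,
    candidates: Iterable[Edge],
    cfg: LagConfig = LagConfig(),
    q: float = 0.01,
) -> nx.DiGraph:
    """Correlation-based alternative: lagged Spearman + BH FDR filtering.

    For each candidate edge the maximum lagged rank correlation is kept with
    the analytic Spearman p-value at that lag; edges surviving the
    Benjamini-Hochberg procedure at level ``q`` (default 1% FDR) are weighted
    by |rho|.
    """
    kept = _clean_candidates(expr, candidates)
    graph = nx.DiGraph()
    if not kept:
        return graph
    picker = lagged_spearman if cfg.signed_spearman else lagged_spearman_abs
    rows = []
    for src, tgt in kept:
        x = normalize_series(expr.loc[src].to_numpy(float))
        y = normalize_series(expr.loc[tgt].to_numpy(float))
        _, best_lag, best_rho = picker(x, y, cfg.lags)
        n_eff = x.size - best_lag
        pval = stats.spearmanr(x[: x.size - best_lag] if best_lag else x,
                               y[best_lag:]).pvalue
        rows.append((src, tgt, best_lag, best_rho, n_eff, float(pval)))
    pvals = np.array([max(r[5], np.finfo(float).tiny) for r in rows])
    mask = bh_fdr(pvals, q)
    for (src, tgt, lag, rho, _, pval), ok in zip(rows, mask):
        if ok:
            graph.add_edge(src, tgt, weight=abs(rho), rho=rho, lag=lag, pvalue=pval)
    return graph


def results_to_frame(results: Iterable[EdgeTestResult]) -> pd.DataFrame:
    """Tabulate edge test results (one row per candidate edge)."""
    rows = [
        {
            "source": r.source,
            "target": r.target,
            "chosen_lag": r.chosen_lag,
            "te": r.te,
            "robust_distance": r.robust_distance,
            "empirical_p": r.empirical_p,
            "accepted": r.accepted,
            "best_rho_lag": r.best_rho_lag,
            "best_rho": r.best_rho,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
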