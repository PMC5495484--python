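"""Hypercube min-max ant optimization for the influence maximization problem.

The goal is the size-K source set S maximizing the diffusion network cover
Omega (ties broken by summed source out-weight).  Ants construct candidate
sets by sequentially sampling nodes with probability proportional to
``u_i**alpha * r_i**beta`` (u_i: summed outgoing edge weight, r_i: pheromone),
renormalizing after every draw.  Each ant's set is refined by stochastic
hill climbing over member/non-member swaps.  Three solutions are tracked —
iteration-best, restart-best and overall-best — and the pheromone vector is
pulled toward their weighted membership average:

    r(t+1) = r(t) + d * (r_avg - r(t)),
    r_avg_i = f1*[i in b_iter] + f2*[i in b_restart] + f3*[i in b_best]

with f1 + f2 + f3 = 1, so pheromones stay inside the unit hypercube.  The
fraction schedule shifts weight from the iteration-best toward the restart-
and overall-best solutions as the pheromone vector converges.  A restart
ends when the pheromone sum changes by less than ``convergence_tol``.

Exhaustive and greedy reference optimizers are included as oracles and
baselines for validating the metaheuristic on small instances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb
from typing import Hashable, List, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .diffusion import CoverScore, DiffusionScorer

__all__ = [
    "AcoParams",
    "Solution",
    "SLOW_PRESET",
    "FAST_PRESET",
    "construct_solution",
    "hill_climb",
    "pheromone_update",
    "run_imp",
    "exhaustive_imp",
    "greedy_imp",
    "rank_influence",
]

logger = logging.getLogger(__name__)

# staged (f1, f2, f3) weights: early updates follow the iteration-best only,
# later stages lean on the restart-best and overall-best solutions
DEFAULT_FRACTION_SCHEDULE: Tuple[Tuple[float, float, float], ...] = (
    (1.0, 0.0, 0.0),
    (2.0 / 3.0, 1.0 / 3.0, 0.0),
    (1.0 / 3.0, 2.0 / 3.0, 0.0),
    (0.0, 1.0 / 3.0, 2.0 / 3.0),
)
# pheromone convergence-factor thresholds that advance the schedule stages
_STAGE_THRESHOLDS = (0.4, 0.6, 0.8)


@dataclass(frozen=True)
class AcoParams:
    """Ant-optimization parameters.

    ``learn_rate`` is the pheromone learning rate d in
    ``r(t+1) = r(t) + d (r_avg - r(t))``; the "evaporation rate" of min-max
    ant systems maps onto this same constant here because the update rule
    has no separate decay step.
    """

    n_ants: int = 64
    n_restarts: int = 8
    local_steps: int = 32
    learn_rate: float = 0.2
    alpha: float = 1.0
    beta: float = 1.0
    convergence_tol: float = 1e-4
    fraction_schedule: Tuple[Tuple[float, float, float], ...] = DEFAULT_FRACTION_SCHEDULE
    max_iters: int = 10_000

    def __post_init__(self) -> None:
        if not (0.0 < self.learn_rate <= 1.0):
            raise ValueError("learn_rate must be in (0, 1]")
        for f in self.fraction_schedule:
            if any(x < 0 for x in f) or abs(sum(f) - 1.0) > 1e-12:
                raise ValueError("each fraction stage must be nonnegative and sum to 1")
        if min(self.n_ants, self.n_restarts, self.max_iters) < 1 or self.local_steps < 0:
            raise ValueError("counts must be positive (local_steps may be 0)")


# "slow" setting: more restarts/ants/local steps for robust, repeatable runs
SLOW_PRESET = AcoParams(n_ants=64, n_restarts=8, local_steps=32)
# "fast" setting: fewer, more stochastic iterations with a shorter run time
FAST_PRESET = AcoParams(n_ants=16, n_restarts=4, local_steps=8)

PRESETS = {"slow": SLOW_PRESET, "fast": FAST_PRESET}


@dataclass(frozen=True)
class Solution:
    """A size-K source set with its cover score."""

    nodes: frozenset
    score: CoverScore

    def sorted_nodes(self) -> List[Hashable]:
        return sorted(self.nodes, key=str)


def construct_solution(
    u: np.ndarray,
    r: np.ndarray,
    k: int,
    rng: np.random.Generator,
    alpha: float = 1.0,
    beta: float = 1.0,
) -> np.ndarray:
    """Sample K distinct node indices with probability ~ u^alpha * r^beta.

    Nodes are drawn one at a time without replacement, renormalizing after
    each draw.  If every remaining node has zero probability while slots are
    left, the remaining draws fall back to uniform sampling (logged).
    """
    n = u.size
    if k > n:
        raise ValueError(f"K={k} exceeds number of nodes {n}")
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.power(u, alpha) * np.power(r, beta)
    w = np.where(np.isfinite(w), w, 0.0).astype(float)
    chosen = np.empty(k, dtype=np.intp)
    for slot in range(k):
        total = w.sum()
        if total <= 0:
            logger.debug("degenerate sampling weights; uniform fallback")
            # uniform over nodes not chosen yet
            mask = np.ones(n, dtype=bool)
            mask[chosen[:slot]] = False
            pool = np.flatnonzero(mask)
            chosen[slot:] = rng.choice(pool, size=k - slot, replace=False)
            return chosen
        # inverse-CDF draw (cheaper than rng.choice with a p vector)
        pick = int(np.searchsorted(np.cumsum(w), rng.random() * total, side="right"))
        pick = min(pick, n - 1)
        chosen[slot] = pick
        w[pick] = 0.0
    return chosen


def hill_climb(
    nodes: np.ndarray,
    scorer: DiffusionScorer,
    steps: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, CoverScore]:
    """Stochastic hill climbing over size-preserving swap moves.

    Each step removes a random member and adds a random non-member; the swap
    is kept only when it strictly improves the (omega, tiebreak)
    lexicographic score.  Exactly ``steps`` candidate swaps are evaluated.
    """
    n = len(scorer.nodes)
    current = sorted(int(i) for i in nodes)
    key = tuple(current)
    best = scorer.score_key(key)
    k = len(current)
    if steps == 0 or k == 0 or k == n:
        return np.array(current, dtype=np.intp), best
    members = set(current)
    # pre-drawn random numbers keep the inner loop cheap
    out_draws = rng.integers(0, k, size=steps)
    in_draws = iter(rng.integers(0, n, size=4 * steps).tolist())
    for step in range(steps):
        out_node = key[out_draws[step]]
        in_node = None
        while in_node is None:
            for cand_in in in_draws:
                if cand_in not in members:
                    in_node = cand_in
                    break
            else:  # refill the rejection-sampling pool
                in_draws = iter(rng.integers(0, n, size=4 * steps).tolist())
        cand_members = members - {out_node} | {in_node}
        cand_key = tuple(sorted(cand_members))
        cand_score = scorer.score_key(cand_key)
        if cand_score > best:
            members = cand_members
            key = cand_key
            best = cand_score
    return np.array(key, dtype=np.intp), best


def pheromone_update(
    r: np.ndarray,
    fractions: Tuple[float, float, float],
    learn_rate: float,
    b_iter: np.ndarray,
    b_restart: np.ndarray,
    b_best: np.ndarray,
) -> np.ndarray:
    """One hypercube min-max pheromone update; result stays in [0, 1]."""
    f1, f2, f3 = fractions
    r_avg = np.zeros_like(r)
    for f, members in ((f1, b_iter), (f2, b_restart), (f3, b_best)):
        if f:
            r_avg[members] += f
    r_new = r + learn_rate * (r_avg - r)
    return np.clip(r_new, 0.0, 1.0)


def _convergence_factor(r: np.ndarray) -> float:
    """0 when all pheromones are 0.5; 1 when all have saturated to 0 or 1."""
    if r.size == 0:
        return 1.0
    return float(2.0 * (np.maximum(r, 1.0 - r).mean() - 0.5))


def _stage(cf: float) -> int:
    stage = 0
    for thr in _STAGE_THRESHOLDS:
        if cf >= thr:
            stage += 1
    return stage


def run_imp(
    graph: nx.DiGraph,
    k: int,
    params: AcoParams = SLOW_PRESET,
    seed: int | np.random.Generator = 0,
    scorer: DiffusionScorer | None = None,
    theta: float = 1e-4,
) -> Solution:
    """Search for the size-K source set with maximal network cover.

    Runs ``n_restarts`` independent pheromone convergences; in each
    iteration every ant constructs a candidate set, hill-climbs it, and the
    three-best solutions drive the pheromone update.  A restart ends when
    the pheromone sum changes less than ``convergence_tol`` (or after
    ``max_iters`` iterations).  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if scorer is None:
        scorer = DiffusionScorer(graph, theta=theta)
    n = len(scorer.nodes)
    if n == 0 or k == 0:
        return Solution(frozenset(), CoverScore(0, 0.0, 0))
    if k > n:
        raise ValueError(f"K={k} exceeds graph size {n}")

    u = scorer.u
    overall: Tuple[np.ndarray, CoverScore] | None = None
    for _restart in range(params.n_restarts):
        r = np.full(n, 0.5)
        restart_best: Tuple[np.ndarray, CoverScore] | None = None
        prev_sum = r.sum()
        for _it in range(params.max_iters):
            iter_best: Tuple[np.ndarray, CoverScore] | None = None
            for _ant in range(params.n_ants):
                cand = construct_solution(u, r, k, rng, params.alpha, params.beta)
                cand, score = hill_climb(cand, scorer, params.local_steps, rng)
                if iter_best is None or score > iter_best[1]:
                    iter_best = (cand, score)
            assert iter_best is not None
            if restart_best is None or iter_best[1] > restart_best[1]:
                restart_best = iter_best
            if overall is None or restart_best[1] > overall[1]:
                overall = restart_best
            fractions = params.fraction_schedule[
                min(_stage(_convergence_factor(r)), len(params.fraction_schedule) - 1)
            ]
            r = pheromone_update(
                r,
                fractions,
                params.learn_rate,
                iter_best[0],
                restart_best[0],
                overall[0],
            )
            new_sum = r.sum()
            if abs(new_sum - prev_sum) < params.convergence_tol:
                break
            prev_sum = new_sum
    assert overall is not None
    nodes = frozenset(scorer.nodes[i] for i in overall[0])
    return Solution(nodes=nodes, score=overall[1])


def exhaustive_imp(
    graph: nx.DiGraph,
    k: int,
    scorer: DiffusionScorer | None = None,
    theta: float = 1e-4,
    guard: int = 10**6,
) -> Solution:
    """Global optimum by enumerating all C(|V|, K) source sets (test oracle)."""
    if scorer is None:
        scorer = DiffusionScorer(graph, theta=theta)
    n = len(scorer.nodes)
    if k == 0 or n == 0:
        return Solution(frozenset(), CoverScore(0, 0.0, 0))
    if k > n:
        raise ValueError(f"K={k} exceeds graph size {n}")
    if comb(n, k) > guard:
        raise ValueError(f"C({n},{k}) exceeds enumeration guard {guard}")
    best_set: Tuple[int, ...] | None = None
    best_score: CoverScore | None = None
    for subset in itertools.combinations(range(n), k):
        score = scorer.score_indices(subset)
        if best_score is None or score > best_score:
            best_set, best_score = subset, score
    assert best_set is not None and best_score is not None
    return Solution(
        nodes=frozenset(scorer.nodes[i] for i in best_set), score=best_score
    )


def greedy_imp(
    graph: nx.DiGraph,
    k: int,
    scorer: DiffusionScorer | None = None,
    theta: float = 1e-4,
) -> Solution:
    """Greedy baseline: iteratively add the node with largest marginal gain.

    Marginal ties are broken by the larger tie-break weight, then by node
    order; never better than the exhaustive optimum.
    """
    if scorer is None:
        scorer = DiffusionScorer(graph, theta=theta)
    n = len(scorer.nodes)
    if k > n:
        raise ValueError(f"K={k} exceeds graph size {n}")
    chosen: List[int] = []
    for _ in range(k):
        best_i, best_score = None, None
        for i in range(n):
            if i in chosen:
                continue
            score = scorer.score_indices(chosen + [i])
            if best_score is None or score > best_score:
                best_i, best_score = i, score
        assert best_i is not None and best_score is not None
        chosen.append(best_i)
    score = scorer.score_indices(chosen) if chosen else CoverScore(0, 0.0, 0)
    return Solution(nodes=frozenset(scorer.nodes[i] for i in chosen), score=score)


def rank_influence(
    graph: nx.DiGraph,
    k_range: Sequence[int] = range(1, 51),
    reps: int = 3,
    params: AcoParams = SLOW_PRESET,
    seed: int = 0,
    theta: float = 1e-4,
) -> pd.DataFrame:
    """Influence ranking: selection counts over solutions for K in a range.

    For every (K, repetition) pair one optimization run produces a size-K
    solution; a node's influence is the number of solutions containing it.
    The returned table has columns ``node``, ``count``, ``mean_count`` (per
    repetition), ``tiebreak`` (node out-weight) and ``rank``, sorted by
    count descending with ties broken by tiebreak then node id.
    """
    k_range = [int(k) for k in k_range]
    scorer = DiffusionScorer(graph, theta=theta)
    if k_range and max(k_range) > len(scorer.nodes):
        raise ValueError("max K exceeds number of nodes")
    ss = np.random.SeedSequence(seed)
    streams = iter(ss.spawn(len(k_range) * reps))
    counts: dict = {v: 0 for v in scorer.nodes}
    for rep in range(reps):
        for k in k_range:
            sol = run_imp(
                graph, k, params, seed=np.random.default_rng(next(streams)),
                scorer=scorer,
            )
            for v in sol.nodes:
                counts[v] += 1
    rows = [
        {
            "node": v,
            "count": c,
            "mean_count": c / reps,
            "tiebreak": scorer.u[scorer.model.index[v]],
        }
        for v, c in counts.items()
    ]
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["count", "tiebreak", "node"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
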