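"""Absorbing random-walk diffusion and the network-cover influence score.

A weighted digraph is turned into a row-stochastic transition matrix
``p_ij = w_ij / sum_j w_ij`` (nodes without out-edges get an all-zero row:
the walk stops at dead ends).  Given a partition of the vertices into a
source set S and its complement T, walks start in S and move through T until
they reach a dead end or step back into S.  The expected number of visits
from source i to transit node j is the matrix H solving

    H = P_ST + H P_TT      <=>      H (I - P_TT) = P_ST,

solved here column-wise as (I - P_TT)' H' = P_ST' with an iterative sparse
solver (avoiding the explicit inverse), with an automatic fallback to the
truncated recurrence when the iterative solver does not converge.

A transit node j is "covered" when its visit mass exceeds a small threshold
theta (default 1e-4); the influence score Omega of a source set is the count
of covered nodes, with the summed out-edge weight of the sources as a
tie-breaker between solutions producing identical covers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Hashable, Iterable, List, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse.linalg import lgmres

__all__ = [
    "TransitionModel",
    "VisitMatrix",
    "CoverScore",
    "transition_matrix",
    "expected_visits",
    "visits_oracle",
    "influence_score",
    "DiffusionScorer",
    "SolverError",
]


class SolverError(RuntimeError):
    """Raised when neither the iterative solver nor the fallback converges."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual {residual:.3e})")
        self.residual = residual


@dataclass
class TransitionModel:
    """Row-stochastic transition matrix with its node ordering."""

    matrix: sparse.csr_matrix
    nodes: List[Hashable]

    def __post_init__(self) -> None:
        self.index: Dict[Hashable, int] = {v: i for i, v in enumerate(self.nodes)}

    @property
    def n(self) -> int:
        return len(self.nodes)

    def partition(self, sources: Iterable[Hashable]) -> Tuple[np.ndarray, np.ndarray]:
        """Index arrays (S, T) for a source set and its complement."""
        s_set = set(sources)
        missing = s_set - set(self.nodes)
        if missing:
            raise KeyError(f"sources not in graph: {sorted(map(str, missing))}")
        if not s_set:
            raise ValueError("source set must be nonempty")
        s_idx = np.array(sorted(self.index[v] for v in s_set), dtype=np.intp)
        mask = np.ones(self.n, dtype=bool)
        mask[s_idx] = False
        return s_idx, np.flatnonzero(mask)


@dataclass
class VisitMatrix:
    """Expected visits H (|S| x |T|) with the row/column node orderings."""

    H: np.ndarray
    sources: List[Hashable]
    transit: List[Hashable]


@dataclass(frozen=True)
class CoverScore:
    """Influence score: covered transit nodes, with a weight-sum tie-breaker.

    Orders lexicographically by (omega, tiebreak); comparisons are written
    out explicitly because they sit on the optimizer's hot path.
    """

    omega: int
    tiebreak: float
    n_sources: int = 0

    @property
    def total_cover(self) -> int:
        """Cover including the sources themselves."""
        return self.omega + self.n_sources

    def __eq__(self, other) -> bool:
        return (self.omega, self.tiebreak) == (other.omega, other.tiebreak)

    def __lt__(self, other) -> bool:
        return (self.omega, self.tiebreak) < (other.omega, other.tiebreak)

    def __gt__(self, other) -> bool:
        return (self.omega, self.tiebreak) > (other.omega, other.tiebreak)

    def __le__(self, other) -> bool:
        return not self.__gt__(other)

    def __ge__(self, other) -> bool:
        return not self.__lt__(other)


def transition_matrix(graph: nx.DiGraph, nodes: Sequence[Hashable] | None = None) -> TransitionModel:
    """Row-normalize a weighted digraph into transition probabilities.

    Each row sums to 1, except rows of nodes without out-edges, which are
    all-zero (dead ends absorb the walk).  Nonpositive weights are an input
    error; self-loops are not allowed.
    """
    if nodes is None:
        nodes = sorted(graph.nodes)
    else:
        nodes = list(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, w in graph.edges(data="weight", default=1.0):
        if u == v:
            raise ValueError(f"self-loop on node {u!r} not allowed")
        if not w > 0:
            raise ValueError(f"nonpositive weight {w!r} on edge {u!r}->{v!r}")
        rows.append(index[u])
        cols.append(index[v])
        vals.append(float(w))
    n = len(nodes)
    W = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    out = np.asarray(W.sum(axis=1)).ravel()
    inv = np.where(out > 0, 1.0 / np.where(out > 0, out, 1.0), 0.0)
    P = sparse.diags(inv) @ W
    return TransitionModel(matrix=P.tocsr(), nodes=nodes)


def expected_visits(
    model: TransitionModel,
    sources: Iterable[Hashable],
    tol: float = 1e-10,
    fallback_steps: int = 100_000,
) -> VisitMatrix:
    """Solve for the expected-visit matrix H of an absorbing walk.

    For each source the sparse asymmetric system (I - P_TT)' h = p is solved
    with LGMRES to a residual of ``tol``; if the solver does not converge the
    truncated recurrence H(t) = P_ST + H(t-1) P_TT is iterated instead.  Tiny
    negative round-off values are clipped to zero.

    Raises
    ------
    SolverError
        If the fallback recurrence also fails to reach ``tol`` (this happens
        when T traps the walk in a recurrent class with no leakage, where the
        expected visit count diverges).
    """
    s_idx, t_idx = model.partition(sources)
    if t_idx.size == 0:
        raise ValueError("transit set T is empty")
    P = model.matrix
    P_ST = P[s_idx][:, t_idx].toarray()
    P_TT = P[t_idx][:, t_idx].tocsr()
    A = (sparse.identity(t_idx.size, format="csr") - P_TT).T.tocsr()
    H = np.empty_like(P_ST)
    need_fallback = False
    for i in range(s_idx.size):
        b = P_ST[i]
        h, info = lgmres(A, b, rtol=min(tol, 1e-12), atol=tol * 1e-2, maxiter=2000)
        if info != 0 or np.linalg.norm(A @ h - b, ord=np.inf) > tol:
            need_fallback = True
            break
        H[i] = h
    if need_fallback:
        H = P_ST.copy()
        resid = np.inf
        for _ in range(fallback_steps):
            H_next = P_ST + H @ P_TT
            resid = float(np.max(np.abs(H_next - H)))
            H = H_next
            if resid < tol:
                break
        else:
            raise SolverError("expected-visit recurrence did not converge", resid)
    np.clip(H, 0.0, None, out=H)
    nodes = model.nodes
    return VisitMatrix(
        H=H,
        sources=[nodes[i] for i in s_idx],
        transit=[nodes[j] for j in t_idx],
    )


def visits_oracle(
    model: TransitionModel, sources: Iterable[Hashable], n_steps: int
) -> VisitMatrix:
    """Truncated-recurrence reference: iterate H(t) = P_ST + H(t-1) P_TT.

    Test oracle for :func:`expected_visits`; entries are monotone
    nondecreasing in ``n_steps`` and converge whenever walks leak out of T.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    s_idx, t_idx = model.partition(sources)
    P = model.matrix
    P_ST = P[s_idx][:, t_idx].toarray()
    P_TT = P[t_idx][:, t_idx].toarray()
    H = P_ST.copy()
    for _ in range(n_steps - 1):
        H = P_ST + H @ P_TT
    nodes = model.nodes
    return VisitMatrix(
        H=H,
        sources=[nodes[i] for i in s_idx],
        transit=[nodes[j] for j in t_idx],
    )


def influence_score(
    visits: VisitMatrix | np.ndarray,
    theta: float = 1e-4,
    aggregation: str = "unique",
    tiebreak: float = 0.0,
    n_sources: int | None = None,
) -> CoverScore:
    """Score a source set by the network cover its diffusion produces.

    With the default ``"unique"`` aggregation a transit node j is covered
    when its total visit mass over all sources exceeds theta — the cover on
    nodes in T.  The ``"pairwise"`` aggregation instead counts every (i, j)
    pair with ``h_ij > theta`` (the literal double sum), which can exceed |T|
    when several sources reach the same node.
    """
    H = visits.H if isinstance(visits, VisitMatrix) else np.asarray(visits)
    if n_sources is None:
        n_sources = H.shape[0]
    if aggregation == "unique":
        omega = int(np.count_nonzero(H.sum(axis=0) > theta))
    elif aggregation == "pairwise":
        omega = int(np.count_nonzero(H > theta))
    else:
        raise ValueError("aggregation must be 'unique' or 'pairwise'")
    return CoverScore(omega=omega, tiebreak=float(tiebreak), n_sources=n_sources)


class DiffusionScorer:
    """Cached influence-score evaluator for repeated source-set queries.

    The optimizer evaluates tens of thousands of candidate source sets on
    one fixed network, so this scorer keeps a dense copy of the transition
    matrix, computes only the *total* visit mass per transit node (a single
    linear solve ``(I - P_TT)' v = colsum(P_ST)`` instead of one per source;
    sufficient for the unique-cover score), and memoizes scores by frozen
    source set.
    """

    def __init__(
        self,
        graph: nx.DiGraph,
        theta: float = 1e-4,
        aggregation: str = "unique",
    ):
        self.model = transition_matrix(graph)
        self.theta = float(theta)
        self.aggregation = aggregation
        self.P = self.model.matrix.toarray()
        self.nodes = self.model.nodes
        # node weight u_i: summed outgoing edge weight (tie-breaker and
        # construction heuristic)
        self.u = np.zeros(len(self.nodes))
        for node, wsum in ((v, sum(w for *_, w in graph.out_edges(v, data="weight", default=1.0))) for v in graph.nodes):
            self.u[self.model.index[node]] = wsum
        self._cache: Dict[Tuple[int, ...], CoverScore] = {}
        self._eye = np.eye(len(self.nodes))

    def score_indices(self, s_indices: Sequence[int]) -> CoverScore:
        """Score a source set given as indices into the node ordering."""
        return self.score_key(tuple(sorted(int(i) for i in s_indices)))

    def score_key(self, key: Tuple[int, ...]) -> CoverScore:
        """Score a source set given as a *sorted* tuple of node indices.

        Hot-path entry point for the optimizer: the tuple is used directly
        as the memoization key, so callers must pass it sorted.
        """
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        s_idx = np.asarray(key, dtype=np.intp)
        mask = np.ones(len(self.nodes), dtype=bool)
        mask[s_idx] = False
        t_idx = np.flatnonzero(mask)
        tiebreak = float(self.u[s_idx].sum())
        if t_idx.size == 0:
            score = CoverScore(0, tiebreak, s_idx.size)
        else:
            P_TT = self.P[np.ix_(t_idx, t_idx)]
            s_vec = self.P[np.ix_(s_idx, t_idx)].sum(axis=0)
            A = self._eye[: t_idx.size, : t_idx.size] - P_TT
            try:
                v = np.linalg.solve(A.T, s_vec)
                if not np.all(np.isfinite(v)):
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                v = self._recurrence(s_vec, P_TT)
            if self.aggregation == "unique":
                omega = int(np.count_nonzero(v > self.theta))
            else:
                vm = expected_visits(self.model, [self.nodes[i] for i in s_idx])
                omega = influence_score(vm, self.theta, "pairwise").omega
            score = CoverScore(omega, tiebreak, s_idx.size)
        self._cache[key] = score
        return score

    @staticmethod
    def _recurrence(s_vec: np.ndarray, P_TT: np.ndarray, steps: int = 500) -> np.ndarray:
        v = s_vec.copy()
        for _ in range(steps):
            v_next = s_vec + v @ P_TT
            if np.max(np.abs(v_next - v)) < 1e-12:
                return v_next
            v = v_next
        return v

    def score(self, source_nodes: Iterable[Hashable]) -> CoverScore:
        """Score a source set given as node identifiers."""
        return self.score_indices([self.model.index[v] for v in source_nodes])
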