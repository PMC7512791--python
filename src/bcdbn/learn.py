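"""Structure learners for transition networks.

Two exact, polynomial-time learners over discrete time-series data:

* :func:`learn_tdbn` — the tree-augmented DBN: every child-slice node gets
  exactly one intra-slice parent (except the root of the tree) plus at most
  ``p`` past parents; the tree is the maximum-weight spanning arborescence
  of the edge-gain graph.
* :func:`learn_transition` — the BFS-consistent learner (bcDBN): the intra
  graph may have in-degree up to ``k`` but every intra edge must point
  forward in the BFS order of the optimal branching.  Because the score is
  decomposable and the order is total, each node's parents can be optimised
  independently and the result is the exact optimum of that search space.

Both learners share the edge weights ``e_ij = s_ij - s_i`` where

    s_i  = max over past sets P (|P| <= p) of phi_i(P),
    s_ij = max over past sets P (|P| <= p) of phi_i(P + {X_j[t+1]}),

the maximisations running over the documented enumeration order (subset size
ascending, then lexicographic), with the first strict improvement kept.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .branching import Branching, bfs_total_order, max_branching
from .model import (
    DBNModel,
    SlicedVariable,
    TimeSeriesDataset,
    TransitionStructure,
    canonical_parents,
)
from .scores import CachedScorer, ScoreSpec, TransitionTable, ofe

__all__ = [
    "LearnConfig",
    "EdgeWeights",
    "enumerate_subsets",
    "past_pool",
    "best_past_set",
    "compute_edge_weights",
    "select_parents",
    "learn_transition",
    "learn_tdbn",
    "learn",
    "structure_score",
    "make_scorer",
]


@dataclass(frozen=True)
class LearnConfig:
    """Learning bounds and options: Markov lag ``m``, at most ``p`` past and
    ``k`` intra parents per node, score criterion, stationarity, and the
    branching mode feeding the BFS order."""

    m: int = 1
    p: int = 1
    k: int = 1
    score: ScoreSpec = field(default_factory=ScoreSpec)
    stationary: bool = True
    branching_mode: str = "spanning"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.p < 0 or self.k < 0:
            raise ValueError("p and k must be >= 0")
        if self.branching_mode not in ("spanning", "forest"):
            raise ValueError(f"unknown branching mode {self.branching_mode!r}")


@dataclass
class EdgeWeights:
    """Best past-parent scores and the intra-edge gain matrix.

    ``s[i]`` and ``best_past[i]`` are the optimum of phi_i over past sets;
    ``s_pair[j, i]`` and ``best_past_pair[(j, i)]`` the optimum with
    ``X_j[t+1]`` forced in; ``e[j, i] = s_pair[j, i] - s[i]``.
    """

    s: np.ndarray
    best_past: tuple[frozenset, ...]
    s_pair: np.ndarray
    best_past_pair: dict[tuple[int, int], frozenset]
    e: np.ndarray


def enumerate_subsets(pool: Sequence, max_size: int) -> Iterator[tuple]:
    """All subsets of ``pool`` of size 0..max_size, size ascending then
    lexicographic in pool order; the empty set comes first."""
    if max_size < 0:
        raise ValueError("max_size must be >= 0")
    for size in range(min(max_size, len(pool)) + 1):
        yield from itertools.combinations(pool, size)


def past_pool(n: int, m: int) -> list[SlicedVariable]:
    """The n*m inter-slice candidate parents, ordered slice-major then by
    attribute index."""
    return [SlicedVariable(a, s) for s in range(m) for a in range(n)]


def make_scorer(
    data: TimeSeriesDataset,
    cfg: LearnConfig,
    window_t: Optional[int] = None,
) -> CachedScorer:
    """A memoised local-score evaluator for one learning problem."""
    table = TransitionTable(data, cfg.m, stationary=cfg.stationary, window_t=window_t)
    return CachedScorer(table, cfg.score)


def _best_past(
    scorer: CachedScorer, cfg: LearnConfig, child: int, extra_intra: Optional[int]
) -> tuple[frozenset, float]:
    n = scorer.table.n
    extra = () if extra_intra is None else (SlicedVariable(extra_intra, cfg.m),)
    best_set: Optional[tuple] = None
    best = -np.inf
    for subset in enumerate_subsets(past_pool(n, cfg.m), cfg.p):
        sc = scorer.score(child, canonical_parents(subset + extra))
        if sc > best:
            best, best_set = sc, subset
    return frozenset(best_set), best


def best_past_set(
    child: int,
    extra_intra: Optional[int],
    data: TimeSeriesDataset,
    cfg: LearnConfig,
    window_t: Optional[int] = None,
    scorer: Optional[CachedScorer] = None,
) -> tuple[frozenset, float]:
    """Optimal set of at most ``p`` past parents for ``child`` (``s_i``), or
    with the intra-slice node ``extra_intra`` forced in as well (``s_ij``).

    Ties are resolved by the first maximiser in enumeration order (strict
    improvement over a running max started at -inf)."""
    if extra_intra == child:
        raise ValueError("extra_intra must differ from the child")
    if scorer is None:
        scorer = make_scorer(data, cfg, window_t)
    return _best_past(scorer, cfg, child, extra_intra)


def compute_edge_weights(
    data: TimeSeriesDataset,
    cfg: LearnConfig,
    window_t: Optional[int] = None,
    scorer: Optional[CachedScorer] = None,
) -> EdgeWeights:
    """Fill ``s_i``, ``s_ij`` and the gain matrix ``e_ij = s_ij - s_i`` for
    every ordered pair of child-slice nodes."""
    if scorer is None:
        scorer = make_scorer(data, cfg, window_t)
    n = scorer.table.n
    s = np.zeros(n)
    best_past: list[frozenset] = []
    s_pair = np.zeros((n, n))
    best_past_pair: dict[tuple[int, int], frozenset] = {}
    for i in range(n):
        bset, bs = _best_past(scorer, cfg, i, None)
        s[i] = bs
        best_past.append(bset)
        for j in range(n):
            if j == i:
                continue
            pset, ps = _best_past(scorer, cfg, i, j)
            s_pair[j, i] = ps
            best_past_pair[(j, i)] = pset
    e = s_pair - s[None, :]
    np.fill_diagonal(e, 0.0)
    return EdgeWeights(
        s=s, best_past=tuple(best_past), s_pair=s_pair,
        best_past_pair=best_past_pair, e=e,
    )


def _select(
    scorer: CachedScorer,
    cfg: LearnConfig,
    child: int,
    ancestors: frozenset,
) -> tuple[frozenset, frozenset, float]:
    n = scorer.table.n
    anc = sorted(ancestors)
    pool = past_pool(n, cfg.m)
    best_past: Optional[tuple] = None
    best_intra: Optional[tuple] = None
    best = -np.inf
    for past in enumerate_subsets(pool, cfg.p):
        for intra in enumerate_subsets(anc, cfg.k):
            parents = canonical_parents(
                past + tuple(SlicedVariable(j, cfg.m) for j in intra)
            )
            sc = scorer.score(child, parents)
            if sc > best:
                best, best_past, best_intra = sc, past, intra
    return frozenset(best_past), frozenset(best_intra), best


def select_parents(
    child: int,
    ancestors: Iterable[int],
    data: TimeSeriesDataset,
    cfg: LearnConfig,
    window_t: Optional[int] = None,
    scorer: Optional[CachedScorer] = None,
) -> tuple[frozenset, frozenset, float]:
    """Jointly optimal (past set <= p, intra set <= k within ``ancestors``)
    parents of ``child``; a root (no ancestors) always gets an empty intra
    set.  First maximiser in nested enumeration order (past outer, intra
    inner) wins."""
    ancestors = frozenset(ancestors)
    if child in ancestors:
        raise ValueError("a node cannot be its own ancestor")
    if scorer is None:
        scorer = make_scorer(data, cfg, window_t)
    return _select(scorer, cfg, child, ancestors)


def learn_transition(
    data: TimeSeriesDataset,
    cfg: LearnConfig,
    window_t: Optional[int] = None,
    scorer: Optional[CachedScorer] = None,
) -> TransitionStructure:
    """Learn one bcDBN transition network.

    Pipeline: edge gains -> maximum branching -> BFS total order -> per-node
    exact parent selection constrained to BFS ancestors.  The result is
    acyclic by construction and optimal among all structures with <= p past
    parents and intra graphs BFS-consistent with the found order.
    """
    if scorer is None:
        scorer = make_scorer(data, cfg, window_t)
    n = scorer.table.n
    ew = compute_edge_weights(data, cfg, window_t, scorer=scorer)
    br = max_branching(ew.e, cfg.branching_mode)
    order = bfs_total_order(br)
    past: list[frozenset] = [frozenset()] * n
    intra: list[frozenset] = [frozenset()] * n
    for i in range(n):
        ps, ins, _ = _select(scorer, cfg, i, order.ancestors[i])
        past[i], intra[i] = ps, ins
    struct = TransitionStructure(n, cfg.m, tuple(past), tuple(intra))
    struct.validate_bounds(cfg.p, cfg.k)
    return struct


def learn_tdbn(
    data: TimeSeriesDataset,
    cfg: LearnConfig,
    window_t: Optional[int] = None,
    scorer: Optional[CachedScorer] = None,
) -> TransitionStructure:
    """Learn the tree-augmented (tDBN) transition network: intra edges are
    the maximum spanning arborescence of the gain graph; each non-root child
    keeps the cached past set maximising ``s_ij`` for its tree parent, the
    root the one maximising ``s_i``.  ``cfg.k`` is ignored."""
    if scorer is None:
        scorer = make_scorer(data, cfg, window_t)
    n = scorer.table.n
    ew = compute_edge_weights(data, cfg, window_t, scorer=scorer)
    br = max_branching(ew.e, "spanning")
    past: list[frozenset] = []
    intra: list[frozenset] = []
    for i in range(n):
        parent = br.parent[i]
        if parent is None:
            past.append(ew.best_past[i])
            intra.append(frozenset())
        else:
            past.append(ew.best_past_pair[(parent, i)])
            intra.append(frozenset({parent}))
    return TransitionStructure(n, cfg.m, tuple(past), tuple(intra))


def structure_score(
    structure: TransitionStructure,
    data: TimeSeriesDataset,
    cfg: LearnConfig,
    window_t: Optional[int] = None,
    scorer: Optional[CachedScorer] = None,
) -> float:
    """Total (decomposable) score of a structure: sum of per-node local
    scores under ``cfg.score``."""
    if scorer is None:
        scorer = make_scorer(data, cfg, window_t)
    return sum(
        scorer.score(i, structure.parents_of(i)) for i in range(structure.n)
    )


def learn(
    data: TimeSeriesDataset,
    cfg: LearnConfig,
    algorithm: str = "bcdbn",
) -> DBNModel:
    """Learn a full DBN: transition structure(s) plus OFE-estimated CPTs.

    Stationary learning pools all windows into one transition network;
    non-stationary learning fits one network per window ``t = m-1 .. T-1``.
    The prior over the initial ``m`` slices is not learned (left uniform).
    """
    if algorithm not in ("bcdbn", "tdbn"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if data.T < cfg.m:
        raise ValueError(f"need T >= m, got T={data.T}, m={cfg.m}")
    fit = learn_transition if algorithm == "bcdbn" else learn_tdbn
    windows = [None] if cfg.stationary else list(range(cfg.m - 1, data.T))
    transitions = []
    for wt in windows:
        scorer = make_scorer(data, cfg, wt)
        struct = fit(data, cfg, wt, scorer=scorer)
        cpts = {
            i: ofe(scorer.table.counts(i, struct.parents_of(i)), cfg.score.pseudo_count)
            for i in range(data.n)
        }
        transitions.append((struct, cpts))
    return DBNModel(
        attrs=list(data.attrs),
        m=cfg.m,
        stationary=cfg.stationary,
        transitions=transitions,
    )
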