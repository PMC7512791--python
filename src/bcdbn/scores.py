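"""Sufficient statistics and decomposable scoring functions.

For a child node and a candidate parent set, the sufficient statistics are
the counts ``N_ijk`` (child in state k while the parents take configuration
j) over the transition rows of the data.  From these the package computes

* the observed frequency estimate (OFE) ``theta_ijk = N_ijk / N_ij`` — the
  maximum-likelihood CPT estimate,
* the local log-likelihood ``LL_i = sum_jk N_ijk ln(N_ijk / N_ij)``,
* the local MDL score ``LL_i - (1/2) ln(N) (r_i - 1) q_i``,

all in natural log.  Both scores are decomposable: the network score is the
sum of the per-node local scores, which is what makes the branching-based
learners exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Iterable, Optional

import numpy as np

from .model import (
    CPT,
    SlicedVariable,
    TimeSeriesDataset,
    canonical_parents,
)

__all__ = [
    "TransitionCounts",
    "ScoreSpec",
    "TransitionTable",
    "CachedScorer",
    "count_transitions",
    "ofe",
    "local_ll",
    "local_mdl",
    "local_score",
]


@dataclass(frozen=True)
class ScoreSpec:
    """Which decomposable criterion to use: ``"ll"`` or ``"mdl"``.

    ``pseudo_count`` is used only when exporting CPTs through :func:`ofe`,
    never by the scores themselves.
    """

    criterion: str = "mdl"
    pseudo_count: float = 0.0

    def __post_init__(self) -> None:
        if self.criterion not in ("ll", "mdl"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.pseudo_count < 0:
            raise ValueError("pseudo_count must be non-negative")


@dataclass
class TransitionCounts:
    """Counts N_ijk for one child and one ordered candidate parent set."""

    child: int
    parent_list: tuple[SlicedVariable, ...]
    parent_cards: tuple[int, ...]
    r: int
    counts: np.ndarray  # (q, r) integers
    row_totals: np.ndarray  # (q,)
    total: int  # number of transition rows tallied

    @property
    def q(self) -> int:
        return self.counts.shape[0]


class TransitionTable:
    """Flattened transition rows of a dataset for one learning problem.

    Each row lays out one window of ``m+1`` slices; column ``s*n + a`` holds
    the state of attribute ``a`` at window slice ``s``.  Stationary learning
    pools the rows of every window ``t = m-1 .. T-1`` (``N*(T-m+1)`` rows);
    non-stationary learning keeps the ``N`` rows of a single window.
    """

    def __init__(
        self,
        data: TimeSeriesDataset,
        m: int,
        stationary: bool = True,
        window_t: Optional[int] = None,
    ) -> None:
        if m < 1:
            raise ValueError("Markov lag m must be >= 1")
        if data.T < m:
            raise ValueError(f"need T >= m, got T={data.T}, m={m}")
        self.n = data.n
        self.m = m
        self.cards = data.cards
        v = data.values
        if stationary:
            blocks = [
                v[:, t - m + 1 : t + 2, :].reshape(data.N, (m + 1) * data.n)
                for t in range(m - 1, data.T)
            ]
            self.rows = np.ascontiguousarray(np.concatenate(blocks, axis=0))
        else:
            if window_t is None:
                raise ValueError("window_t is required for non-stationary counting")
            if not (m - 1 <= window_t <= data.T - 1):
                raise ValueError(f"window_t must be in [{m - 1}, {data.T - 1}]")
            self.rows = np.ascontiguousarray(
                v[:, window_t - m + 1 : window_t + 2, :].reshape(data.N, (m + 1) * data.n)
            )
        self.total = self.rows.shape[0]

    def _check_parents(self, child: int, parents: Iterable[SlicedVariable]) -> None:
        for sv in parents:
            if not (0 <= sv.attr < self.n):
                raise ValueError(f"parent attribute {sv.attr} out of range")
            if not (0 <= sv.slice <= self.m):
                raise ValueError(f"parent slice {sv.slice} outside the window")
            if sv.slice == self.m and sv.attr == child:
                raise ValueError("a node cannot be its own intra-slice parent")

    def counts(self, child: int, parent_list: tuple[SlicedVariable, ...]) -> TransitionCounts:
        self._check_parents(child, parent_list)
        r = self.cards[child]
        q = 1
        idx = np.zeros(self.total, dtype=np.int64)
        cards = []
        for sv in parent_list:
            rj = self.cards[sv.attr]
            idx = idx * rj + self.rows[:, sv.slice * self.n + sv.attr]
            q *= rj
            cards.append(rj)
        child_col = self.rows[:, self.m * self.n + child]
        flat = np.bincount(idx * r + child_col, minlength=q * r)
        counts = flat.reshape(q, r)
        return TransitionCounts(
            child=child,
            parent_list=tuple(parent_list),
            parent_cards=tuple(cards),
            r=r,
            counts=counts,
            row_totals=counts.sum(axis=1),
            total=self.total,
        )


def count_transitions(
    data: TimeSeriesDataset,
    m: int,
    child: int,
    parents: Iterable[SlicedVariable],
    stationary: bool = True,
    window_t: Optional[int] = None,
) -> TransitionCounts:
    """Tally N_ijk for ``child`` given ``parents`` over the transition rows.

    Parents are put in canonical (slice, attr) order before counting, so the
    configuration index follows the package-wide mixed-radix convention.
    """
    table = TransitionTable(data, m, stationary=stationary, window_t=window_t)
    return table.counts(child, canonical_parents(parents))


def ofe(counts: TransitionCounts, pseudo_count: float = 0.0) -> CPT:
    """Observed frequency estimate of the CPT, optionally smoothed.

    ``theta_ijk = (N_ijk + pseudo) / (N_ij + r_i * pseudo)``; with no
    pseudo-counts an unobserved configuration row falls back to uniform.
    """
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be non-negative")
    c = counts.counts.astype(float) + pseudo_count
    tot = counts.row_totals.astype(float) + counts.r * pseudo_count
    table = np.empty_like(c)
    empty = tot == 0.0
    table[~empty] = c[~empty] / tot[~empty, None]
    table[empty] = 1.0 / counts.r
    # exact row normalisation for the CPT invariant
    table /= table.sum(axis=1, keepdims=True)
    return CPT(
        child=counts.child,
        parent_list=counts.parent_list,
        parent_cards=counts.parent_cards,
        r=counts.r,
        table=table,
    )


def local_ll(counts: TransitionCounts) -> float:
    """Local log-likelihood at the OFE optimum:
    ``sum_jk N_ijk ln(N_ijk / N_ij)`` with ``0 ln 0 := 0``."""
    c = counts.counts
    nz = c > 0
    ll = float(np.sum(c[nz] * np.log(c[nz])))
    rt = counts.row_totals
    nzr = rt > 0
    ll -= float(np.sum(rt[nzr] * np.log(rt[nzr])))
    return ll


def local_mdl(counts: TransitionCounts, total_rows: int) -> float:
    """Local MDL score: LL minus ``(1/2) ln(N) (r_i - 1) q_i``.

    The penalty is structural — unobserved configurations still count
    toward ``q_i``.
    """
    if total_rows < 1:
        raise ValueError("total_rows must be >= 1")
    penalty = 0.5 * log(total_rows) * (counts.r - 1) * counts.q
    return local_ll(counts) - penalty


def local_score(
    spec: ScoreSpec,
    data: TimeSeriesDataset,
    m: int,
    child: int,
    parents: Iterable[SlicedVariable],
    stationary: bool = True,
    window_t: Optional[int] = None,
) -> float:
    """The per-node local score phi_i(parents, data) for the chosen criterion."""
    counts = count_transitions(data, m, child, parents, stationary, window_t)
    if spec.criterion == "ll":
        return local_ll(counts)
    return local_mdl(counts, counts.total)


class CachedScorer:
    """Memoised local scores over one :class:`TransitionTable`.

    The learner's weight computation and parent selection re-evaluate many
    overlapping parent sets; keys are ``(child, canonical parent tuple)``.
    ``evaluations`` counts cache misses (used to verify polynomial scaling).
    """

    def __init__(self, table: TransitionTable, spec: ScoreSpec) -> None:
        self.table = table
        self.spec = spec
        self._cache: dict[tuple, float] = {}
        self.evaluations = 0

    def score(self, child: int, parents: tuple[SlicedVariable, ...]) -> float:
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        self.evaluations += 1
        counts = self.table.counts(child, parents)
        if self.spec.criterion == "ll":
            val = local_ll(counts)
        else:
            val = local_mdl(counts, self.table.total)
        self._cache[key] = val
        return val
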