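"""Core types for discrete dynamic Bayesian networks.

A dynamic Bayesian network (DBN) over ``n`` discrete attributes factorises the
distribution of a trajectory ``X[0..T]`` into a prior over the first ``m``
slices and, for every window ``{t-m+1..t} -> t+1``, a transition distribution

    P(X[t+1] | X[t-m+1..t]) = prod_i P(X_i[t+1] | Pa(X_i[t+1])),

where ``m`` is the Markov lag.  Each transition network gives every
child-slice node a set of *inter-slice* (past) parents and a set of
*intra-slice* parents within slice ``t+1``; conditional probability tables
(CPTs) parametrise the local distributions.

Conventions used throughout the package:

* State codes are 0-based integers in the order state labels appear in
  :class:`AttributeSpec.values`.
* Within a window, slices are indexed ``0..m`` with ``m`` the child slice.
* Parent configurations are indexed by mixed-radix encoding of the parent
  states in ``parent_list`` order, with the **last** parent as the least
  significant digit.  Parent lists are kept in canonical order: sorted by
  ``(slice, attr)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "AttributeSpec",
    "SlicedVariable",
    "TransitionStructure",
    "CPT",
    "DBNModel",
    "TimeSeriesDataset",
    "canonical_parents",
    "config_index",
    "model_dimension",
    "log_joint",
]


@dataclass(frozen=True)
class AttributeSpec:
    """A named discrete attribute with an ordered set of state labels.

    The position of a label in ``values`` is its integer state code.
    """

    name: str
    values: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(self.values))
        if len(self.values) < 2:
            raise ValueError(f"attribute {self.name!r} needs >= 2 states")
        if len(set(self.values)) != len(self.values):
            raise ValueError(f"attribute {self.name!r} has duplicate state labels")

    @property
    def cardinality(self) -> int:
        return len(self.values)


class SlicedVariable(NamedTuple):
    """An attribute at a window slice: ``slice`` 0 is the oldest slice of the
    window, ``slice == m`` is the child slice."""

    attr: int
    slice: int


def canonical_parents(parents: Iterable[SlicedVariable]) -> tuple[SlicedVariable, ...]:
    """Sort parents by (slice, attr) — the package-wide canonical order."""
    return tuple(sorted(parents, key=lambda sv: (sv.slice, sv.attr)))


def config_index(states: Sequence[int], cards: Sequence[int]) -> int:
    """Mixed-radix index of a parent configuration (last parent = least
    significant digit)."""
    idx = 0
    for s, r in zip(states, cards):
        idx = idx * r + s
    return idx


@dataclass(frozen=True)
class TransitionStructure:
    """Parent sets of the child-slice nodes for one transition window.

    ``past_parents[i]`` are :class:`SlicedVariable` with ``slice < m``;
    ``intra_parents[i]`` are attribute indices within the child slice.
    The intra-slice graph must be acyclic.
    """

    n: int
    m: int
    past_parents: tuple[frozenset, ...]
    intra_parents: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "past_parents", tuple(frozenset(s) for s in self.past_parents)
        )
        object.__setattr__(
            self, "intra_parents", tuple(frozenset(s) for s in self.intra_parents)
        )
        if len(self.past_parents) != self.n or len(self.intra_parents) != self.n:
            raise ValueError("parent tuples must have one entry per attribute")
        for i in range(self.n):
            for sv in self.past_parents[i]:
                if not (0 <= sv.attr < self.n and 0 <= sv.slice < self.m):
                    raise ValueError(f"past parent {sv} of node {i} out of window")
            for j in self.intra_parents[i]:
                if not (0 <= j < self.n) or j == i:
                    raise ValueError(f"invalid intra parent {j} of node {i}")
        self.intra_topological_order()  # raises on a cycle

    def validate_bounds(self, p: int, k: int) -> None:
        """Check the in-degree bounds: <= p past and <= k intra parents."""
        for i in range(self.n):
            if len(self.past_parents[i]) > p:
                raise ValueError(f"node {i} has > {p} past parents")
            if len(self.intra_parents[i]) > k:
                raise ValueError(f"node {i} has > {k} intra parents")

    def intra_topological_order(self) -> list[int]:
        """Topological order of the intra-slice graph (Kahn; ties by index)."""
        indeg = [len(self.intra_parents[i]) for i in range(self.n)]
        children: list[list[int]] = [[] for _ in range(self.n)]
        for i in range(self.n):
            for j in self.intra_parents[i]:
                children[j].append(i)
        ready = sorted(i for i in range(self.n) if indeg[i] == 0)
        order: list[int] = []
        while ready:
            v = ready.pop(0)
            order.append(v)
            changed = False
            for c in children[v]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
                    changed = True
            if changed:
                ready.sort()
        if len(order) != self.n:
            raise ValueError("intra-slice graph has a cycle")
        return order

    def parents_of(self, child: int) -> tuple[SlicedVariable, ...]:
        """All parents of ``child`` in canonical order (intra parents get
        slice ``m``)."""
        svs = list(self.past_parents[child]) + [
            SlicedVariable(j, self.m) for j in self.intra_parents[child]
        ]
        return canonical_parents(svs)

    def edge_count(self) -> int:
        return sum(
            len(self.past_parents[i]) + len(self.intra_parents[i])
            for i in range(self.n)
        )

    @classmethod
    def empty(cls, n: int, m: int) -> "TransitionStructure":
        return cls(n, m, tuple(frozenset() for _ in range(n)), tuple(frozenset() for _ in range(n)))


@dataclass
class CPT:
    """Conditional probability table of one child node.

    ``table`` has one row per parent configuration (``q`` rows, mixed-radix
    indexed in ``parent_list`` order) and one column per child state.
    """

    child: int
    parent_list: tuple[SlicedVariable, ...]
    parent_cards: tuple[int, ...]
    r: int
    table: np.ndarray

    def __post_init__(self) -> None:
        self.parent_list = tuple(self.parent_list)
        self.parent_cards = tuple(int(c) for c in self.parent_cards)
        self.table = np.asarray(self.table, dtype=float)
        q = int(np.prod(self.parent_cards)) if self.parent_cards else 1
        if self.table.shape != (q, self.r):
            raise ValueError(
                f"CPT table shape {self.table.shape} != ({q}, {self.r})"
            )
        if np.any(self.table < 0):
            raise ValueError("CPT entries must be non-negative")
        if not np.allclose(self.table.sum(axis=1), 1.0, rtol=0.0, atol=1e-12):
            raise ValueError("CPT rows must sum to 1 within 1e-12")

    @property
    def q(self) -> int:
        return self.table.shape[0]

    def row_index(self, parent_states: Sequence[int]) -> int:
        return config_index(parent_states, self.parent_cards)


@dataclass
class DBNModel:
    """A discrete DBN: attributes, Markov lag, optional prior network and one
    (stationary) or several (one per window) transition networks with CPTs.

    ``transitions`` is a list of ``(TransitionStructure, {child: CPT})``
    pairs; a stationary model holds exactly one.  ``prior`` optionally holds
    an intra-slice-only network for the initial slices as a
    ``(TransitionStructure, {child: CPT})`` pair with ``m == 0``; when absent,
    the initial ``m`` slices are treated as independent uniform.
    """

    attrs: list[AttributeSpec]
    m: int
    stationary: bool
    transitions: list[tuple[TransitionStructure, dict[int, CPT]]]
    prior: Optional[tuple[TransitionStructure, dict[int, CPT]]] = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("Markov lag m must be >= 1")
        if self.stationary and len(self.transitions) != 1:
            raise ValueError("stationary model must hold exactly one transition network")
        n = self.n
        cards = self.cards
        for struct, cpts in self.transitions:
            if struct.n != n or struct.m != self.m:
                raise ValueError("transition structure shape mismatch")
            for i in range(n):
                cpt = cpts[i]
                expect = struct.parents_of(i)
                if tuple(cpt.parent_list) != expect:
                    raise ValueError(f"CPT of node {i} disagrees with structure")
                if cpt.r != cards[i]:
                    raise ValueError(f"CPT of node {i} has wrong cardinality")

    @property
    def n(self) -> int:
        return len(self.attrs)

    @property
    def cards(self) -> tuple[int, ...]:
        return tuple(a.cardinality for a in self.attrs)

    def transition(self, window_t: Optional[int] = None) -> tuple[TransitionStructure, dict[int, CPT]]:
        """The transition network of window ``window_t`` (a stationary model
        ignores the argument)."""
        if self.stationary:
            return self.transitions[0]
        if window_t is None:
            raise ValueError("window_t required for a non-stationary model")
        return self.transitions[window_t - (self.m - 1)]


def model_dimension(model: DBNModel, window_t: Optional[int] = None) -> int:
    """Number of free parameters of one transition network,
    ``sum_i (r_i - 1) * q_i``."""
    struct, _ = model.transition(window_t)
    cards = model.cards
    dim = 0
    for i in range(model.n):
        q = 1
        for sv in struct.parents_of(i):
            q *= cards[sv.attr]
        dim += (cards[i] - 1) * q
    return dim


def log_joint(model: DBNModel, window: np.ndarray, window_t: Optional[int] = None) -> float:
    """Log-probability of one window's child slice given its past,
    ``sum_i ln P(X_i[t+1] = x_i | parents)``; ``-inf`` if any factor is 0.

    ``window`` is an ``(m+1, n)`` integer array of state codes covering the
    whole window, oldest slice first.
    """
    window = np.asarray(window, dtype=np.int64)
    if window.shape != (model.m + 1, model.n):
        raise ValueError(f"window must have shape ({model.m + 1}, {model.n})")
    cards = model.cards
    for a in range(model.n):
        col = window[:, a]
        if np.any(col < 0) or np.any(col >= cards[a]):
            raise ValueError(f"state code out of range for attribute {a}")
    struct, cpts = model.transition(window_t)
    total = 0.0
    for i in range(model.n):
        cpt = cpts[i]
        states = [window[sv.slice, sv.attr] for sv in cpt.parent_list]
        p = cpt.table[cpt.row_index(states), window[model.m, i]]
        if p <= 0.0:
            return -math.inf
        total += math.log(p)
    return total


@dataclass
class TimeSeriesDataset:
    """N subjects observed over slices ``0..T`` for ``n`` discrete attributes.

    ``values`` is an ``(N, T+1, n)`` integer array of state codes.
    """

    values: np.ndarray
    attrs: list[AttributeSpec]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 3:
            raise ValueError("values must be an (N, T+1, n) array")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("need at least one subject and one slice")
        if self.values.shape[2] != len(self.attrs):
            raise ValueError("attribute list does not match data width")
        for a, spec in enumerate(self.attrs):
            col = self.values[:, :, a]
            if col.min() < 0 or col.max() >= spec.cardinality:
                raise ValueError(f"state code out of range for attribute {spec.name!r}")

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1] - 1

    @property
    def n(self) -> int:
        return self.values.shape[2]

    @property
    def cards(self) -> tuple[int, ...]:
        return tuple(a.cardinality for a in self.attrs)
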