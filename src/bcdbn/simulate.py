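"""Synthetic transition networks, CPTs and forward-sampled trajectories.

The generator emulates the benchmarking protocol used throughout the
package's recovery experiments: draw a random stationary transition
structure obeying the in-degree bounds (p past, k intra), fill its CPTs with
Dirichlet-distributed rows — optionally forcing a dominant state so that the
dependencies are strong enough to be recoverable at realistic sample sizes —
and forward-sample N independent trajectories.

Structure modes
---------------
``complete_intra``
    Nodes are put in a uniformly random total order; the node at rank i
    takes its min(k, i) nearest predecessors as intra parents.  With k=2
    this is the "complete" BFS-consistent 2-graph used in the recovery
    benchmarks.
``random``
    The node at rank i takes a uniform subset of its predecessors of a
    uniform size in 0..min(k, i).
``tree``
    Each non-first node takes exactly one uniform predecessor: a random
    spanning tree with intra in-degree 1 (the tDBN-structured truth).

Past parents are drawn per node as a uniform subset of the n*m inter-slice
candidates: of size exactly p in the ``complete_intra`` and ``tree`` modes
(saturated, "complete" truths) and of a uniform size in 0..p in ``random``
mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .learn import past_pool
from .model import (
    CPT,
    AttributeSpec,
    DBNModel,
    SlicedVariable,
    TimeSeriesDataset,
    TransitionStructure,
    canonical_parents,
)

__all__ = [
    "GeneratorConfig",
    "random_structure",
    "random_cpts",
    "build_model",
    "random_model",
    "sample_dataset",
    "default_attrs",
]

STRUCTURE_MODES = ("complete_intra", "random", "tree")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-network generator.

    ``r`` is the shared state count of all attributes; ``concentration`` the
    symmetric Dirichlet parameter of CPT rows; ``dominance``, when set,
    rescales one uniformly chosen state per row to probability >= dominance
    (the strong-dependence regime; 1.0 gives deterministic CPTs).
    """

    n: int
    m: int = 1
    p: int = 2
    k: int = 2
    r: int = 2
    structure_mode: str = "complete_intra"
    concentration: float = 1.0
    dominance: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1 or self.r < 2:
            raise ValueError("need n >= 1, m >= 1, r >= 2")
        if self.p < 0 or self.k < 0:
            raise ValueError("p and k must be >= 0")
        if self.structure_mode not in STRUCTURE_MODES:
            raise ValueError(f"unknown structure mode {self.structure_mode!r}")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.dominance is not None and not (1.0 / self.r < self.dominance <= 1.0):
            raise ValueError("dominance must lie in (1/r, 1]")


def default_attrs(n: int, r: int) -> list[AttributeSpec]:
    return [AttributeSpec(f"X{i}", tuple(str(v) for v in range(r))) for i in range(n)]


def random_structure(
    cfg: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> TransitionStructure:
    """Draw a random transition structure obeying the (p, k) bounds, with
    intra edges consistent with a uniformly random total order."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    order = list(rng.permutation(cfg.n))
    pool = past_pool(cfg.n, cfg.m)
    past = [frozenset()] * cfg.n
    intra = [frozenset()] * cfg.n
    for rank, node in enumerate(order):
        preds = order[:rank]
        limit = min(cfg.k, rank)
        if cfg.structure_mode == "complete_intra":
            chosen = preds[rank - limit:]
        elif cfg.structure_mode == "tree":
            chosen = [preds[rng.integers(rank)]] if rank > 0 else []
        else:
            size = int(rng.integers(limit + 1))
            chosen = list(rng.choice(preds, size=size, replace=False)) if size else []
        intra[node] = frozenset(int(j) for j in chosen)
        if cfg.structure_mode == "random":
            psize = int(rng.integers(cfg.p + 1))
        else:
            # "complete" regimes saturate the inter-slice in-degree: every
            # node draws exactly p past parents (the learner's bound then
            # coincides with the truth's in-degree).
            psize = min(cfg.p, len(pool))
        pick = rng.choice(len(pool), size=psize, replace=False) if psize else []
        past[node] = frozenset(pool[int(i)] for i in pick)
    return TransitionStructure(cfg.n, cfg.m, tuple(past), tuple(intra))


def random_cpts(
    structure: TransitionStructure,
    cfg: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> dict[int, CPT]:
    """Sample a CPT per child: rows ~ Dirichlet(concentration); with
    ``dominance`` set, a uniformly chosen state per row is raised to at
    least that probability and the rest rescaled."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    cpts: dict[int, CPT] = {}
    for child in range(structure.n):
        parent_list = structure.parents_of(child)
        cards = tuple(cfg.r for _ in parent_list)
        q = int(np.prod(cards)) if cards else 1
        rows = rng.dirichlet(np.full(cfg.r, cfg.concentration), size=q)
        if cfg.dominance is not None:
            # Rescale a uniformly chosen state into [dominance, 1] and
            # renormalise the rest.  The map is strictly monotone in the
            # original probability, so distinct Dirichlet rows stay distinct:
            # every parent keeps a non-null effect (the sampled CPT is a.s.
            # faithful to its graph), which a hard floor at `dominance`
            # would destroy by collapsing rows onto identical values.
            for j in range(q):
                s = int(rng.integers(cfg.r))
                target = cfg.dominance + (1.0 - cfg.dominance) * rows[j, s]
                rest = 1.0 - rows[j, s]
                scale = (1.0 - target) / rest if rest > 0 else 0.0
                rows[j] *= scale
                rows[j, s] = target
        rows /= rows.sum(axis=1, keepdims=True)
        cpts[child] = CPT(
            child=child, parent_list=parent_list, parent_cards=cards,
            r=cfg.r, table=rows,
        )
    return cpts


def build_model(
    structure: TransitionStructure, cpts: dict[int, CPT], r: int
) -> DBNModel:
    """Wrap a stationary transition structure and its CPTs in a DBNModel
    with default attribute names X0..X{n-1}."""
    return DBNModel(
        attrs=default_attrs(structure.n, r),
        m=structure.m,
        stationary=True,
        transitions=[(structure, cpts)],
    )


def random_model(
    cfg: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> DBNModel:
    """Random structure + random CPTs, ready to sample from."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    structure = random_structure(cfg, rng)
    cpts = random_cpts(structure, cfg, rng)
    return build_model(structure, cpts, cfg.r)


def sample_dataset(
    model: DBNModel,
    N: int,
    T: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> TimeSeriesDataset:
    """Forward-sample N independent trajectories over slices 0..T.

    The initial m slices come from the model's prior (independent uniform
    when absent); each later slice is drawn child-by-child in a topological
    order of the intra graph, conditioning on the realised parents.
    """
    if not model.stationary:
        raise ValueError("sampling is implemented for stationary models")
    if T < model.m:
        raise ValueError(f"need T >= m, got T={T}, m={model.m}")
    if N < 1:
        raise ValueError("need N >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    n, m = model.n, model.m
    cards = model.cards
    values = np.zeros((N, T + 1, n), dtype=np.int64)

    def draw(cpt: CPT, idx: np.ndarray) -> np.ndarray:
        cum = np.cumsum(cpt.table[idx], axis=1)
        return np.argmax(rng.random((idx.shape[0], 1)) < cum, axis=1)

    if model.prior is None:
        for t in range(m):
            for a in range(n):
                values[:, t, a] = rng.integers(cards[a], size=N)
    else:
        pstruct, pcpts = model.prior
        topo = pstruct.intra_topological_order()
        for t in range(m):
            for child in topo:
                cpt = pcpts[child]
                idx = np.zeros(N, dtype=np.int64)
                for sv in cpt.parent_list:
                    idx = idx * cards[sv.attr] + values[:, t, sv.attr]
                values[:, t, child] = draw(cpt, idx)

    struct, cpts = model.transitions[0]
    topo = struct.intra_topological_order()
    for t in range(m, T + 1):
        base = t - m  # absolute slice of window slice 0
        for child in topo:
            cpt = cpts[child]
            idx = np.zeros(N, dtype=np.int64)
            for sv in cpt.parent_list:
                idx = idx * cards[sv.attr] + values[:, base + sv.slice, sv.attr]
            values[:, t, child] = draw(cpt, idx)
    return TimeSeriesDataset(values=values, attrs=list(model.attrs))
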