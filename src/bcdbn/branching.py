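"""Maximum branchings and the BFS total order over them.

The learners weight every candidate intra-slice edge ``X_j[t+1] -> X_i[t+1]``
with the score gain ``e_ij = s_ij - s_i`` and then extract a maximum-weight
branching with the Chu-Liu/Edmonds algorithm.  Two modes are supported:

* ``"spanning"`` — the maximum-weight spanning arborescence over the best
  choice of a single root (every non-root node gets exactly one intra
  parent); this is the tree the tDBN learner uses and the default source of
  the BFS order.
* ``"forest"`` — the literal maximum branching: edges with non-positive gain
  may be dropped, so the result can have several roots or no edges at all.

The breadth-first traversal of the branching, with ties at equal depth broken
by ascending node index and multiple roots seeded in ascending index order,
yields a total order; a node's *ancestors* are all nodes visited strictly
before it.  Tie-breaking everywhere prefers the smaller source index so that
identical inputs give identical outputs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["Branching", "BFSOrder", "max_branching", "bfs_total_order"]


@dataclass(frozen=True)
class Branching:
    """A directed forest: each node has at most one parent."""

    parent: tuple[Optional[int], ...]
    total_weight: float

    @property
    def n(self) -> int:
        return len(self.parent)

    @property
    def roots(self) -> tuple[int, ...]:
        return tuple(i for i, p in enumerate(self.parent) if p is None)

    def edges(self) -> list[tuple[int, int]]:
        return [(p, v) for v, p in enumerate(self.parent) if p is not None]


@dataclass(frozen=True)
class BFSOrder:
    """Total order of nodes from a BFS of a branching.

    ``order[r]`` is the node visited r-th, ``rank`` is the inverse
    permutation, and ``ancestors[i]`` is the full BFS prefix before node i.
    """

    order: tuple[int, ...]
    rank: tuple[int, ...]
    ancestors: tuple[frozenset, ...]


def _best_incoming(nodes, edges, root):
    """For every non-root node pick the max-weight incoming edge (ties ->
    smaller source).  Returns None if some node has no incoming edge."""
    best = {}
    for v in nodes:
        if v == root:
            continue
        bu = None
        bw = 0.0
        for u in nodes:
            if u == v:
                continue
            w = edges.get((u, v))
            if w is None:
                continue
            if bu is None or w > bw or (w == bw and u < bu):
                bu, bw = u, w
        if bu is None:
            return None
        best[v] = bu
    return best


def _find_cycle(best):
    """A cycle in the chosen-parent map, as a list of nodes, or None."""
    colour = {}
    for start in best:
        if start in colour:
            continue
        path = []
        v = start
        while v in best and colour.get(v) is None:
            colour[v] = "grey"
            path.append(v)
            v = best[v]
        if colour.get(v) == "grey":
            return path[path.index(v):]
        for u in path:
            colour[u] = "black"
    return None


def _cle(nodes, edges, root, next_id):
    """Chu-Liu/Edmonds maximum arborescence rooted at ``root``.

    ``edges`` maps (u, v) -> weight.  Returns {child: parent} over the
    original node ids, or None when some node is unreachable.
    """
    best = _best_incoming(nodes, edges, root)
    if best is None:
        return None
    cycle = _find_cycle(best)
    if cycle is None:
        return best
    cyc = set(cycle)
    c = next_id
    new_nodes = [x for x in nodes if x not in cyc] + [c]
    new_edges = {}
    choice = {}
    for (u, v), w in edges.items():
        if u in cyc and v in cyc:
            continue
        if v in cyc:
            key = (u, c)
            w2 = w - edges[(best[v], v)]
            if (
                key not in new_edges
                or w2 > new_edges[key]
                or (w2 == new_edges[key] and (u, v) < choice[key])
            ):
                new_edges[key] = w2
                choice[key] = (u, v)
        elif u in cyc:
            key = (c, v)
            if (
                key not in new_edges
                or w > new_edges[key]
                or (w == new_edges[key] and (u, v) < choice[key])
            ):
                new_edges[key] = w
                choice[key] = (u, v)
        else:
            new_edges[(u, v)] = w
            choice[(u, v)] = (u, v)
    sub = _cle(new_nodes, new_edges, root, next_id + 1)
    if sub is None:
        return None
    result = {}
    entering = None
    for v, u in sub.items():
        ou, ov = choice[(u, v)]
        result[ov] = ou
        if v == c:
            entering = ov
    for v in cyc:
        if v != entering:
            result[v] = best[v]
    return result


def max_branching(weights: np.ndarray, mode: str = "spanning") -> Branching:
    """Maximum-weight branching of a dense weight matrix.

    ``weights[j, i]`` is the weight of the directed edge ``j -> i``; the
    diagonal is ignored.  ``mode="spanning"`` returns the best single-root
    spanning arborescence (n-1 edges, negative weights allowed);
    ``mode="forest"`` returns the unconstrained maximum branching, in which
    non-positive edges are never forced in.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weights must be a square matrix")
    if not np.all(np.isfinite(W[~np.eye(W.shape[0], dtype=bool)])) and W.shape[0] > 1:
        raise ValueError("off-diagonal weights must be finite")
    n = W.shape[0]
    if mode not in ("spanning", "forest"):
        raise ValueError(f"unknown branching mode {mode!r}")
    if n == 1:
        return Branching(parent=(None,), total_weight=0.0)
    edges = {
        (u, v): float(W[u, v]) for u in range(n) for v in range(n) if u != v
    }
    if mode == "spanning":
        best_map = None
        best_w = -np.inf
        for root in range(n):
            res = _cle(list(range(n)), edges, root, n)
            if res is None:
                continue
            w = sum(edges[(u, v)] for v, u in res.items())
            if w > best_w:
                best_w, best_map = w, res
        parent = tuple(best_map.get(v) for v in range(n))
        return Branching(parent=parent, total_weight=float(best_w))
    # forest mode: virtual root with zero-weight edges to every node; a
    # virtual edge chosen for v means "v keeps no intra parent".
    virt = n
    aug = dict(edges)
    for v in range(n):
        aug[(virt, v)] = 0.0
    res = _cle(list(range(n + 1)), aug, virt, n + 1)
    parent = tuple(
        (res[v] if res.get(v) is not None and res[v] != virt else None)
        for v in range(n)
    )
    total = sum(edges[(p, v)] for v, p in enumerate(parent) if p is not None)
    return Branching(parent=parent, total_weight=float(total))


def bfs_total_order(branching: Branching) -> BFSOrder:
    """BFS order of a branching: roots seeded in ascending index order, the
    frontier expanded FIFO with children in ascending index order."""
    n = branching.n
    children: list[list[int]] = [[] for _ in range(n)]
    roots = []
    for v, p in enumerate(branching.parent):
        if p is None:
            roots.append(v)
        else:
            children[p].append(v)
    if n > 0 and not roots:
        raise ValueError("branching has a cycle: no roots")
    queue = deque(sorted(roots))
    order: list[int] = []
    seen = [False] * n
    for r in queue:
        seen[r] = True
    while queue:
        v = queue.popleft()
        order.append(v)
        for c in sorted(children[v]):
            if seen[c]:
                raise ValueError("branching has a cycle")
            seen[c] = True
            queue.append(c)
    if len(order) != n:
        raise ValueError("branching has a cycle")
    rank = [0] * n
    for r, v in enumerate(order):
        rank[v] = r
    ancestors = tuple(frozenset(order[:rank[i]]) for i in range(n))
    return BFSOrder(order=tuple(order), rank=tuple(rank), ancestors=ancestors)
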