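"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's vectorised code paths:
scores are tallied with pure-python Counters and optimal branchings are
found by exhaustive enumeration, so that agreement with the package is a
genuine cross-check.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from bcdbn.model import AttributeSpec, TimeSeriesDataset


def binary_attrs(n: int) -> list[AttributeSpec]:
    return [AttributeSpec(f"X{i}", ("0", "1")) for i in range(n)]


def random_dataset(rng, n: int, N: int, T: int = 1, r: int = 2) -> TimeSeriesDataset:
    attrs = [AttributeSpec(f"X{i}", tuple(str(v) for v in range(r))) for i in range(n)]
    values = rng.integers(0, r, size=(N, T + 1, n))
    return TimeSeriesDataset(values=values, attrs=attrs)


def copy_dataset(rng, n: int, N: int, T: int = 1) -> TimeSeriesDataset:
    """Each attribute deterministically copies its own previous value."""
    values = np.zeros((N, T + 1, n), dtype=np.int64)
    values[:, 0, :] = rng.integers(0, 2, size=(N, n))
    for t in range(1, T + 1):
        values[:, t, :] = values[:, t - 1, :]
    return TimeSeriesDataset(values=values, attrs=binary_attrs(n))


def naive_local_score(rows, cards, m, n, child, parents, criterion) -> float:
    """Pure-python local LL/MDL over flattened window rows (column s*n+a)."""
    groups: Counter = Counter()
    totals: Counter = Counter()
    for w in rows:
        j = tuple(w[sv.slice * n + sv.attr] for sv in parents)
        k = w[m * n + child]
        groups[(j, k)] += 1
        totals[j] += 1
    ll = sum(c * math.log(c / totals[j]) for (j, k), c in groups.items())
    if criterion == "mdl":
        q = 1
        for sv in parents:
            q *= cards[sv.attr]
        ll -= 0.5 * math.log(len(rows)) * (cards[child] - 1) * q
    return ll


def brute_spanning_arborescence(W: np.ndarray) -> float:
    """Max total weight over all rooted spanning arborescences (exhaustive)."""
    n = W.shape[0]
    best = -math.inf
    for root in range(n):
        others = [v for v in range(n) if v != root]
        choices = [[u for u in range(n) if u != v] for v in others]
        for combo in itertools.product(*choices):
            parent = dict(zip(others, combo))
            # acyclic <=> every node reaches the root
            ok = True
            for v in others:
                seen = set()
                x = v
                while x != root:
                    if x in seen:
                        ok = False
                        break
                    seen.add(x)
                    x = parent[x]
                if not ok:
                    break
            if ok:
                w = sum(W[u, v] for v, u in parent.items())
                best = max(best, w)
    return best


def brute_max_branching(W: np.ndarray) -> float:
    """Max total weight over all branchings (each node: parent or none)."""
    n = W.shape[0]
    best = -math.inf
    choices = [[None] + [u for u in range(n) if u != v] for v in range(n)]
    for combo in itertools.product(*choices):
        ok = True
        for v in range(n):
            seen = set()
            x = v
            while combo[x] is not None:
                x = combo[x]
                if x in seen:
                    ok = False
                    break
                seen.add(x)
            if not ok:
                break
        if not ok:
            continue
        w = sum(W[u, v] for v, u in enumerate(combo) if u is not None)
        best = max(best, w)
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
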