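"""Ranking comparison and robustness/vulnerability quantification.

The *intersection distance* between two ranked lists averages, over
prefix depths ``i = 1..k``, the normalized symmetric difference of the
two depth-``i`` prefixes::

    isim_k(x, y) = (1/k) * sum_{i=1..k} |x_{1..i} Δ y_{1..i}| / (2i)

It is 0 for identical lists and approaches 1 for disjoint ones.

Robustness is measured through the relative size of the largest
connected component along a removal trajectory, ``sigma(i/N)``; the
R-index is its mean over full removal and the V-index the complement
``V = 1/2 - R``.  R is maximal, ``(1/2)(1 - 1/N)``, for complete graphs
and of order ``1/N`` for stars attacked hub-first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import UsageError
from .graph_core import Network

__all__ = [
    "RankingComparison",
    "RobustnessCurve",
    "intersection_distance",
    "sigma_curve",
    "r_index",
    "v_index",
]


@dataclass(frozen=True)
class RankingComparison:
    """``per_prefix[i-1]`` is isim_i; ``value`` is isim_k."""

    k: int
    per_prefix: np.ndarray
    value: float


def intersection_distance(
    x: Sequence, y: Sequence, k: int | None = None
) -> RankingComparison:
    """Prefix-averaged normalized symmetric difference of two ranked lists.

    ``k`` defaults to the common length of the lists.  Entries within
    each list must be distinct; prefixes of equal depth have equal
    size, so ``|X Δ Y| = 2 (i - |X ∩ Y|)`` and the overlap can be
    tracked incrementally.
    """
    x = list(x)
    y = list(y)
    if k is None:
        k = min(len(x), len(y))
    if k < 1 or k > len(x) or k > len(y):
        raise UsageError(f"prefix depth k={k} exceeds a list length")
    if len(set(x[:k])) != k or len(set(y[:k])) != k:
        raise UsageError("ranked lists must not contain repeated entries")
    seen_x: set = set()
    seen_y: set = set()
    overlap = 0
    terms = np.empty(k)
    for i in range(1, k + 1):
        xi, yi = x[i - 1], y[i - 1]
        if xi == yi:
            overlap += 1
        else:
            if xi in seen_y:
                overlap += 1
            if yi in seen_x:
                overlap += 1
            seen_x.add(xi)
            seen_y.add(yi)
        terms[i - 1] = (i - overlap) / i  # |sym.diff| / (2i)
    per_prefix = np.cumsum(terms) / np.arange(1, k + 1)
    return RankingComparison(k=k, per_prefix=per_prefix, value=float(per_prefix[-1]))


@dataclass
class RobustnessCurve:
    """``sigma[i-1]`` is the LCC fraction after ``i`` removals."""

    n: int
    sigma: np.ndarray
    order: list[int]

    @property
    def complete(self) -> bool:
        """Does the trajectory remove every present node?"""
        return len(self.order) == self.n


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = np.arange(n)
        self.size = np.ones(n, dtype=np.int64)

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> int:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return int(self.size[ri])
        if self.size[ri] < self.size[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        self.size[ri] += self.size[rj]
        return int(self.size[ri])


def sigma_curve(g: Network, order: Sequence[int]) -> RobustnessCurve:
    """Largest-component fraction after each removal of ``order``.

    Computed by replaying the removals backwards with a union-find:
    nodes are re-inserted in reverse order, each union only grows the
    maximum component, so a single backward sweep yields every prefix
    state of the forward removal in near-linear total time.  The result
    is identical to recomputing the LCC from scratch after each step.
    """
    order = [int(i) for i in order]
    if len(set(order)) != len(order):
        raise UsageError("removal order contains repeated nodes")
    present = g.present_mask
    for i in order:
        if not (0 <= i < g.n_total and present[i]):
            raise UsageError(f"node {i} in removal order is not present")
    n = g.n_present
    adj = g.adjacency
    active = np.zeros(g.n_total, dtype=bool)
    uf = _UnionFind(g.n_total)
    max_size = 0
    indptr, indices = adj.indptr, adj.indices

    def activate(i: int) -> int:
        best = 1
        for j in indices[indptr[i] : indptr[i + 1]]:
            if active[j]:
                best = max(best, uf.union(i, int(j)))
        return best

    survivors = present.copy()
    survivors[order] = False
    for i in np.flatnonzero(survivors):
        active[i] = True
        max_size = max(max_size, activate(int(i)))
    sizes_after = np.empty(len(order) + 1, dtype=np.int64)
    sizes_after[len(order)] = max_size
    for k in range(len(order) - 1, -1, -1):
        i = order[k]
        active[i] = True
        max_size = max(max_size, activate(i))
        sizes_after[k] = max_size
    sigma = sizes_after[1:] / n
    return RobustnessCurve(n=n, sigma=sigma, order=order)


def r_index(curve: RobustnessCurve) -> float:
    """Mean of sigma over a full-removal trajectory.

    A partial curve is refused: R compares whole trajectories, and its
    ``[~1/N, (1/2)(1-1/N)]`` range only holds for full removal.
    """
    if not curve.complete:
        raise UsageError(
            f"R-index requires full removal: curve covers {len(curve.order)} "
            f"of {curve.n} nodes"
        )
    return float(curve.sigma.mean())


def v_index(curve: RobustnessCurve) -> float:
    """Vulnerability index ``V = 1/2 - R``."""
    return 0.5 - r_index(curve)
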