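"""Exact walk counting on small graphs — the test surface for the
locality theory behind correlation attacks.

Removing node *i* from a graph lowers the total communicability of a
surviving node *j* by exactly the weighted count of walks that leave
*j* and pass through *i*::

    TC_after(j) = TC_before(j) - sum_{k >= s} C_k(i, j) / k!

where ``C_k(i, j)`` is the number of length-``k`` walks from *j*
through *i* and ``s = dist(i, j)`` (no shorter walk can touch *i*).
Every node has at most ``n - 1`` neighbors, so ``C_k`` is at most the
total walk count ``(n-1)^k <= n^k`` (attained on complete graphs,
where ``C_k = (n-1)^k - (n-2)^k`` exactly); the series therefore
converges and its tail after a truncation ``K`` is bounded by
``sum_{k > K} n^k / k!``.  The drop vanishes as the distance grows,
which is why a far-away runner-up keeps its rank after a removal.

Counts are computed by integer dynamic programming with Python
arbitrary-precision integers, so they are exact at any length; the
module is a diagnostic oracle, not a scalable algorithm, and enforces
small-size caps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import UsageError
from .graph_core import Network

__all__ = [
    "WalkDropReport",
    "count_walks_through",
    "count_closed_walks_through",
    "verify_tc_drop",
    "verify_sc_drop",
    "tail_bound",
]

#: exact-arithmetic caps: DP over all nodes and lengths stays trivial here.
MAX_NODES = 30
MAX_LENGTH = 120


@dataclass(frozen=True)
class WalkDropReport:
    """Walk-count accounting for one removal as seen from one node."""

    i: int
    j: int
    s: float
    counts: list[int]
    tc_before: float
    tc_after: float
    truncated_sum: float
    tail_bound: float

    @property
    def drop(self) -> float:
        return self.tc_before - self.tc_after

    @property
    def residual(self) -> float:
        """|observed drop - truncated series|; must be <= tail_bound."""
        return abs(self.drop - self.truncated_sum)


def _adjacency_lists(g: Network) -> list[list[int]]:
    a = g.adjacency
    return [
        a.indices[a.indptr[i] : a.indptr[i + 1]].tolist() for i in range(g.n_total)
    ]


def _walk_vector_steps(
    neigh: list[list[int]], start: int, k_max: int, avoid: int | None
) -> list[int]:
    """Total number of walks of length 1..k_max from ``start``.

    ``avoid`` excises one node (walks may not visit it at all).
    Integer DP: x[v] = number of length-t walks from start ending at v.
    """
    n = len(neigh)
    x = [0] * n
    x[start] = 1
    totals: list[int] = []
    for _ in range(k_max):
        nxt = [0] * n
        for v, cnt in enumerate(x):
            if cnt == 0 or v == avoid:
                continue
            for w in neigh[v]:
                if w != avoid:
                    nxt[w] += cnt
        x = nxt
        totals.append(sum(x))
    return totals


def _closed_walk_steps(
    neigh: list[list[int]], start: int, k_max: int, avoid: int | None
) -> list[int]:
    """Number of closed walks of length 1..k_max from ``start`` back to it."""
    n = len(neigh)
    x = [0] * n
    x[start] = 1
    closed: list[int] = []
    for _ in range(k_max):
        nxt = [0] * n
        for v, cnt in enumerate(x):
            if cnt == 0 or v == avoid:
                continue
            for w in neigh[v]:
                if w != avoid:
                    nxt[w] += cnt
        x = nxt
        closed.append(x[start])
    return closed


def _check_caps(g: Network, k: int) -> None:
    if g.n_present > MAX_NODES:
        raise UsageError(
            f"exact walk counting capped at {MAX_NODES} present nodes "
            f"(got {g.n_present})"
        )
    if not 1 <= k <= MAX_LENGTH:
        raise UsageError(f"walk length {k} outside [1, {MAX_LENGTH}]")


def count_walks_through(g: Network, j: int, i: int, k: int) -> int:
    """Exact number of length-``k`` walks starting at ``j`` through ``i``.

    Computed as (walks of length k from j) minus (walks of length k
    from j avoiding i); both counts are exact integers.
    """
    if i == j:
        raise UsageError("via node must differ from the start node")
    _check_caps(g, k)
    g._require_present(i)
    g._require_present(j)
    neigh = _adjacency_lists(g)
    all_walks = _walk_vector_steps(neigh, j, k, avoid=None)
    avoiding = _walk_vector_steps(neigh, j, k, avoid=i)
    return all_walks[k - 1] - avoiding[k - 1]


def count_closed_walks_through(g: Network, j: int, i: int, k: int) -> int:
    """Exact number of closed length-``k`` walks at ``j`` through ``i``."""
    if i == j:
        raise UsageError("via node must differ from the start node")
    _check_caps(g, k)
    g._require_present(i)
    g._require_present(j)
    neigh = _adjacency_lists(g)
    all_closed = _closed_walk_steps(neigh, j, k, avoid=None)
    avoiding = _closed_walk_steps(neigh, j, k, avoid=i)
    return all_closed[k - 1] - avoiding[k - 1]


def tail_bound(n: int, k_trunc: int, terms: int = 400) -> float:
    """Upper bound on the truncated series tail, from ``C_k <= n^k``:
    ``sum_{k > K} n^k / k!``."""
    return math.fsum(
        math.exp(k * math.log(max(n, 1)) - math.lgamma(k + 1))
        for k in range(k_trunc + 1, k_trunc + terms + 1)
    )


def choose_truncation(n: int, tol: float = 1e-10) -> int:
    """Smallest truncation whose tail bound drops below ``tol``."""
    for k in range(1, MAX_LENGTH + 1):
        if tail_bound(n, k) < tol:
            return k
    return MAX_LENGTH


def _dense_exp(g: Network) -> np.ndarray:
    return scipy.linalg.expm(g.adjacency.toarray())


def verify_tc_drop(
    g: Network, i: int, j: int, k_trunc: int | None = None
) -> WalkDropReport:
    """Account for the TC drop at ``j`` caused by removing ``i``.

    TC before/after comes from a dense matrix exponential (independent
    of the sparse action used elsewhere); the walk series is summed up
    to ``k_trunc`` (default: tail bound below 1e-10).  The report's
    ``residual <= tail_bound`` is the identity under test.
    """
    if i == j:
        raise UsageError("removed node must differ from the observed node")
    g._require_present(i)
    g._require_present(j)
    n = g.n_present
    if n > MAX_NODES:
        raise UsageError(f"verify_tc_drop capped at {MAX_NODES} present nodes")
    if k_trunc is None:
        k_trunc = choose_truncation(n)
    s = g.distance(i, j)
    e_before = _dense_exp(g)
    mask = g.present_mask.astype(float)
    tc_before = float(e_before[j] @ mask)
    after = g.copy().remove_node(i)
    e_after = _dense_exp(after)
    tc_after = float(e_after[j] @ after.present_mask.astype(float))
    neigh = _adjacency_lists(g)
    all_walks = _walk_vector_steps(neigh, j, k_trunc, avoid=None)
    avoiding = _walk_vector_steps(neigh, j, k_trunc, avoid=i)
    counts = [a - b for a, b in zip(all_walks, avoiding)]
    k_start = 1 if not math.isfinite(s) else max(int(s), 1)
    truncated = math.fsum(
        counts[k - 1] / math.factorial(k) for k in range(k_start, k_trunc + 1)
    )
    return WalkDropReport(
        i=i,
        j=j,
        s=s,
        counts=counts,
        tc_before=tc_before,
        tc_after=tc_after,
        truncated_sum=truncated,
        tail_bound=tail_bound(n, k_trunc),
    )


def verify_sc_drop(
    g: Network, i: int, j: int, k_trunc: int | None = None
) -> WalkDropReport:
    """Closed-walk analogue: the drop of ``[e^A]_jj`` when ``i`` is removed."""
    if i == j:
        raise UsageError("removed node must differ from the observed node")
    g._require_present(i)
    g._require_present(j)
    n = g.n_present
    if n > MAX_NODES:
        raise UsageError(f"verify_sc_drop capped at {MAX_NODES} present nodes")
    if k_trunc is None:
        k_trunc = choose_truncation(n)
    s = g.distance(i, j)
    sc_before = float(_dense_exp(g)[j, j])
    after = g.copy().remove_node(i)
    sc_after = float(_dense_exp(after)[j, j])
    neigh = _adjacency_lists(g)
    all_closed = _closed_walk_steps(neigh, j, k_trunc, avoid=None)
    avoiding = _closed_walk_steps(neigh, j, k_trunc, avoid=i)
    counts = [a - b for a, b in zip(all_closed, avoiding)]
    truncated = math.fsum(
        counts[k - 1] / math.factorial(k) for k in range(1, k_trunc + 1)
    )
    return WalkDropReport(
        i=i,
        j=j,
        s=s,
        counts=counts,
        tc_before=sc_before,
        tc_after=sc_after,
        truncated_sum=truncated,
        tail_bound=tail_bound(n, k_trunc),
    )
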