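"""Centrality-ranked node-removal strategies.

Four strategies remove ``M`` nodes in descending centrality order and
differ only in *when* the centrality vector is recomputed:

``simultaneous``
    rank once before the attack; never recompute (1 evaluation).
``sequential``
    recompute after every removal (M evaluations) — the reference
    ranking the cheaper strategies try to approximate.
``threshold``
    recompute once the cumulative *normalized* centrality removed since
    the last (re)computation exceeds a threshold ``gamma``; at
    ``gamma = 0`` this degenerates to the sequential strategy, and for
    ``gamma`` close to 1 to the simultaneous one.
``correlation``
    recompute only when the runner-up in the stale ranking is adjacent
    to the node just removed (or connected to it by a walk of length at
    most ``walk_order``).  Removing a node only perturbs the
    communicability of nodes near it, so a distant runner-up keeps its
    rank; no tuning parameter is needed.

All strategies share the argmax tie rule (smallest node id) and report
the number of centrality evaluations, the cost unit for comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from . import centrality as ct
from .errors import UsageError
from .graph_core import Network

__all__ = [
    "AttackStep",
    "AttackResult",
    "simultaneous_attack",
    "sequential_attack",
    "threshold_attack",
    "correlation_attack",
    "run_attack",
    "fraction_to_count",
    "STRATEGIES",
]


@dataclass(frozen=True)
class AttackStep:
    """Per-removal log record."""

    step: int
    removed: int
    recomputed: bool
    runner_up: int | None = None
    cumulative_mass: float | None = None


@dataclass
class AttackResult:
    """Ordered removal list with its evaluation cost and per-step log."""

    order: list[int]
    evaluations: int
    strategy: str
    measure: str
    steps: list[AttackStep] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    network: Network | None = None

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise UsageError("removal order contains repeated nodes")


def fraction_to_count(delta: float, n: int) -> int:
    """Removal count for a fraction: the smallest integer >= ``delta * n``."""
    if not 0 < delta <= 1:
        raise UsageError(f"removal fraction must be in (0, 1], got {delta}")
    return min(n, math.ceil(delta * n))


def _check_m(g: Network, m: int) -> None:
    if not 1 <= m <= g.n_present:
        raise UsageError(
            f"number of removals M={m} out of range [1, {g.n_present}]"
        )


def _argmax_present(values: np.ndarray, present: np.ndarray) -> int:
    """Largest score among present nodes, ties to the smallest id."""
    masked = np.where(present, values, -np.inf)
    return int(np.argmax(masked))


def _walk_connected(adj: sp.csr_array, i: int, j: int, order: int) -> bool:
    """Is there a walk of length <= ``order`` between i and j?

    Evaluates ``(A)_{ij} + ... + (A^l)_{ij} > 0`` by propagating the
    indicator vector of ``i`` through sparse matvecs, never forming a
    matrix power.
    """
    x = np.zeros(adj.shape[0])
    x[i] = 1.0
    for _ in range(order):
        x = adj @ x
        if x[j] > 0:
            return True
    return False


def simultaneous_attack(
    g: Network, measure: str = "tc", m: int | None = None, inplace: bool = False
) -> AttackResult:
    """Remove the top-``m`` nodes of the initial ranking (1 evaluation)."""
    m = g.n_present if m is None else m
    _check_m(g, m)
    work = g if inplace else g.copy()
    c = ct.compute_centrality(work, measure)
    order = c.top(m, work.present_mask).tolist()
    steps = []
    for k, i in enumerate(order, start=1):
        work.remove_node(i)
        steps.append(AttackStep(step=k, removed=i, recomputed=(k == 1)))
    return AttackResult(
        order=order,
        evaluations=1,
        strategy="simultaneous",
        measure=measure,
        steps=steps,
        params={"M": m},
        network=work,
    )


def sequential_attack(
    g: Network, measure: str = "tc", m: int | None = None, inplace: bool = False
) -> AttackResult:
    """Recompute the ranking after every removal (``m`` evaluations)."""
    m = g.n_present if m is None else m
    _check_m(g, m)
    work = g if inplace else g.copy()
    order: list[int] = []
    steps: list[AttackStep] = []
    for k in range(1, m + 1):
        c = ct.compute_centrality(work, measure)
        i_star = _argmax_present(c.values, work.present_mask)
        work.remove_node(i_star)
        order.append(i_star)
        steps.append(AttackStep(step=k, removed=i_star, recomputed=True))
    return AttackResult(
        order=order,
        evaluations=m,
        strategy="sequential",
        measure=measure,
        steps=steps,
        params={"M": m},
        network=work,
    )


def threshold_attack(
    g: Network,
    measure: str = "tc",
    m: int | None = None,
    gamma: float = 0.01,
    inplace: bool = False,
) -> AttackResult:
    """Recompute when the removed normalized-centrality mass exceeds ``gamma``.

    The working vector is the measure normalized to sum 1 over present
    nodes (removed entries masked to 0 before normalizing).  After each
    removal the removed node's share is added to a running mass; once
    the mass exceeds ``gamma`` the next step recomputes, renormalizes
    and resets the mass.  ``gamma = 0`` triggers a recomputation after
    every removal and therefore reproduces the sequential attack.
    """
    if not 0 <= gamma < 1:
        raise UsageError(f"threshold gamma must be in [0, 1), got {gamma}")
    m = g.n_present if m is None else m
    _check_m(g, m)
    work = g if inplace else g.copy()
    order: list[int] = []
    steps: list[AttackStep] = []
    evaluations = 0
    flag = True
    values = np.zeros(work.n_total)
    cumulative = 0.0
    for k in range(1, m + 1):
        recomputed = False
        if flag:
            c = ct.normalize(ct.compute_centrality(work, measure), work)
            values = c.values.copy()
            cumulative = 0.0
            evaluations += 1
            recomputed = True
        i_star = _argmax_present(values, work.present_mask)
        work.remove_node(i_star)
        cumulative += float(values[i_star])
        values[i_star] = 0.0
        flag = cumulative > gamma
        order.append(i_star)
        steps.append(
            AttackStep(
                step=k, removed=i_star, recomputed=recomputed,
                cumulative_mass=cumulative,
            )
        )
    return AttackResult(
        order=order,
        evaluations=evaluations,
        strategy="threshold",
        measure=measure,
        steps=steps,
        params={"M": m, "gamma": gamma},
        network=work,
    )


def correlation_attack(
    g: Network,
    measure: str = "tc",
    m: int | None = None,
    walk_order: int = 1,
    inplace: bool = False,
) -> AttackResult:
    """Recompute when the runner-up is walk-connected to the removed node.

    The adjacency test uses the matrix state *before* the removal: for
    ``walk_order = 1`` it is the entry ``A[i*, j*]``, for larger orders
    the existence of any walk of length up to ``walk_order``.  With
    fewer than two present nodes there is no runner-up and the flag
    stays off.
    """
    if walk_order < 1:
        raise UsageError(f"walk_order must be >= 1, got {walk_order}")
    m = g.n_present if m is None else m
    _check_m(g, m)
    work = g if inplace else g.copy()
    order: list[int] = []
    steps: list[AttackStep] = []
    evaluations = 0
    adjacent = True
    values = np.zeros(work.n_total)
    for k in range(1, m + 1):
        recomputed = False
        if adjacent:
            c = ct.compute_centrality(work, measure)
            values = c.values.copy()
            values[~work.present_mask] = 0.0
            evaluations += 1
            recomputed = True
        i_star = _argmax_present(values, work.present_mask)
        j_star: int | None = None
        if work.n_present >= 2:
            without = values.copy()
            without[i_star] = -np.inf
            j_star = _argmax_present(without, work.present_mask)
            adjacent = _walk_connected(work.adjacency, i_star, j_star, walk_order)
        else:
            adjacent = False
        work.remove_node(i_star)
        values[i_star] = 0.0
        order.append(i_star)
        steps.append(
            AttackStep(
                step=k, removed=i_star, recomputed=recomputed, runner_up=j_star
            )
        )
    return AttackResult(
        order=order,
        evaluations=evaluations,
        strategy="correlation",
        measure=measure,
        steps=steps,
        params={"M": m, "walk_order": walk_order},
        network=work,
    )


STRATEGIES = {
    "simultaneous": simultaneous_attack,
    "sequential": sequential_attack,
    "threshold": threshold_attack,
    "correlation": correlation_attack,
}


def run_attack(
    g: Network,
    strategy: str,
    measure: str = "tc",
    m: int | None = None,
    **kwargs,
) -> AttackResult:
    """Dispatch by strategy name with strategy-specific keyword arguments."""
    try:
        fn = STRATEGIES[strategy.lower()]
    except KeyError:
        raise UsageError(
            f"unknown strategy {strategy!r}; expected one of {sorted(STRATEGIES)}"
        ) from None
    return fn(g, measure=measure, m=m, **kwargs)
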