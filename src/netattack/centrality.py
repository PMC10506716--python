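"""Matrix-function and degree centralities with an evaluation counter.

Total communicability of node *i* is the *i*-th row sum of ``exp(A)``,
``TC_i = [e^A 1]_i`` — a count of all walks leaving *i* in which a walk
of length *k* is discounted by ``1/k!``.  Subgraph centrality is the
diagonal entry ``SC_i = [e^A]_ii``, the analogous count over closed
walks.  Both are computed without ever forming ``e^A``: TC as the
action of the exponential on the (masked) all-ones vector, SC from the
dense exponential below a size cap and by per-node Lanczos quadrature
above it.

Every call to one of the three measure functions increments a global
evaluation counter.  The number of such evaluations is the cost unit by
which removal strategies are compared: for matrix-function measures a
single evaluation dominates everything else an attack does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

from .errors import UsageError
from .graph_core import Network

logger = logging.getLogger(__name__)

__all__ = [
    "CentralityVector",
    "EvaluationCounter",
    "evaluation_counter",
    "total_communicability",
    "subgraph_centrality",
    "degree_centrality",
    "compute_centrality",
    "normalize",
    "MEASURES",
]

#: dense-exponential size cap for subgraph centrality; above it a
#: per-node Lanczos quadrature estimate is used instead.
SC_DENSE_CAP = 2000

#: Lanczos steps for the large-graph SC estimator.  Gauss quadrature for
#: the exponential converges superlinearly; 40 steps is far below 1e-8
#: relative error for adjacency spectra of sparse graphs.
SC_LANCZOS_STEPS = 40


class EvaluationCounter:
    """Monotone counter of centrality-vector evaluations."""

    def __init__(self) -> None:
        self.count = 0

    def increment(self) -> int:
        self.count += 1
        return self.count

    def reset(self) -> None:
        self.count = 0


#: process-global counter; attacks snapshot it around their runs.
evaluation_counter = EvaluationCounter()


@dataclass(frozen=True)
class CentralityVector:
    """Per-node scores for one measure on one network state.

    ``values`` has length ``n_total``; entries of removed nodes are 0.
    ``eval_id`` is the global counter stamp at computation time.
    """

    values: np.ndarray
    measure: str
    normalized: bool
    eval_id: int

    def top(self, m: int, present_mask: np.ndarray | None = None) -> np.ndarray:
        """Indices of the ``m`` largest scores, ties to the smaller id."""
        vals = self.values
        if present_mask is not None:
            vals = np.where(present_mask, vals, -np.inf)
        order = np.argsort(-vals, kind="stable")
        return order[:m]


def _finalize(g: Network, values: np.ndarray, measure: str) -> CentralityVector:
    values = np.asarray(values, dtype=np.float64).copy()
    values[~g.present_mask] = 0.0
    return CentralityVector(
        values=values,
        measure=measure,
        normalized=False,
        eval_id=evaluation_counter.increment(),
    )


def total_communicability(g: Network) -> CentralityVector:
    """TC over present nodes: the action of ``e^A`` on the masked ones vector.

    Present isolated nodes score exactly 1 (only the empty walk);
    non-isolated nodes score > 1.
    """
    b = g.present_mask.astype(np.float64)
    if g.n_present == 0:
        return _finalize(g, b, "tc")
    vals = expm_multiply(g.adjacency, b)
    return _finalize(g, vals, "tc")


def _lanczos_diagonal(a: sp.csr_array, i: int, steps: int) -> float:
    """Estimate ``[e^A]_ii`` by Lanczos/Gauss quadrature seeded at e_i."""
    n = a.shape[0]
    q = np.zeros(n)
    q[i] = 1.0
    alphas: list[float] = []
    betas: list[float] = []
    q_prev = np.zeros(n)
    beta = 0.0
    for _ in range(steps):
        w = a @ q
        alpha = float(q @ w)
        w -= alpha * q + beta * q_prev
        alphas.append(alpha)
        beta = float(np.linalg.norm(w))
        if beta < 1e-14:
            break
        betas.append(beta)
        q_prev, q = q, w / beta
    t = np.diag(alphas)
    if betas:
        k = len(alphas)
        off = np.array(betas[: k - 1])
        t[np.arange(k - 1), np.arange(1, k)] = off
        t[np.arange(1, k), np.arange(k - 1)] = off
    evals, evecs = scipy.linalg.eigh(t)
    return float(evecs[0] @ (np.exp(evals) * evecs[0]))


def subgraph_centrality(g: Network, dense_cap: int | None = None) -> CentralityVector:
    """SC over present nodes: the diagonal of ``e^A``.

    Dense computation up to ``dense_cap`` nodes (default
    :data:`SC_DENSE_CAP`); per-node Lanczos quadrature above.
    """
    cap = SC_DENSE_CAP if dense_cap is None else dense_cap
    a = g.adjacency
    if g.n_total <= cap:
        vals = np.diag(scipy.linalg.expm(a.toarray()))
    else:
        vals = np.ones(g.n_total)
        for i in g.present_nodes:
            vals[i] = _lanczos_diagonal(a, int(i), SC_LANCZOS_STEPS)
    return _finalize(g, vals, "sc")


def degree_centrality(g: Network) -> CentralityVector:
    """Node degrees, ``[A 1]_i``, on the current masked adjacency."""
    return _finalize(g, g.degrees, "degree")


MEASURES = {
    "tc": total_communicability,
    "sc": subgraph_centrality,
    "degree": degree_centrality,
}


def compute_centrality(g: Network, measure: str) -> CentralityVector:
    """Dispatch by measure name (``tc``, ``sc`` or ``degree``)."""
    try:
        fn = MEASURES[measure.lower()]
    except KeyError:
        raise UsageError(
            f"unknown measure {measure!r}; expected one of {sorted(MEASURES)}"
        ) from None
    return fn(g)


def normalize(c: CentralityVector, g: Network | None = None) -> CentralityVector:
    """Scale scores to sum to 1 over present nodes.

    An all-zero vector (possible for degree after heavy removal) has no
    meaningful ranking left: with the network available it normalizes
    to the uniform distribution over present nodes with a warning,
    otherwise it is a degenerate-input error.
    """
    if c.normalized:
        return c
    total = float(c.values.sum())
    if total > 0:
        return replace(c, values=c.values / total, normalized=True)
    if g is None:
        raise UsageError("cannot normalize an all-zero centrality vector")
    logger.warning(
        "all-zero %s vector: normalizing to uniform over %d present nodes",
        c.measure,
        g.n_present,
    )
    values = g.present_mask / max(g.n_present, 1)
    return replace(c, values=values, normalized=True)
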