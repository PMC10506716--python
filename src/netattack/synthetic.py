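"""Synthetic graph generators for the experiment ensembles.

Two random families mirror the classic toolbox generators used in
attack-tolerance studies: ``erdrey(n, m)``, a uniform random graph with
an exact edge count (Poisson degree distribution for sparse m), and
``pref(n, d)``, preferential attachment with ``d`` edges per new node
(scale-free / heavy-tailed degrees).  Random instances are conditioned
on connectivity by regeneration, so every returned graph is a single
component.  Deterministic test graphs (star, complete, path) round out
the set.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .errors import UsageError
from .graph_core import Network, from_networkx

__all__ = ["erdrey", "pref", "star", "complete", "path", "from_spec"]

_MAX_TRIES = 200


def erdrey(n: int, m: int | None = None, seed=None) -> Network:
    """Uniform random connected graph with exactly ``m`` edges.

    ``m`` defaults to ``4n`` (mean degree 8).  Instances are drawn
    uniformly over simple graphs with ``m`` edges and redrawn until
    connected; for the sparse regimes used here a connected draw occurs
    within a handful of attempts.
    """
    if n < 2:
        raise UsageError(f"need at least 2 nodes, got {n}")
    m = 4 * n if m is None else m
    if not n - 1 <= m <= n * (n - 1) // 2:
        raise UsageError(
            f"edge count m={m} infeasible for a connected graph on {n} nodes"
        )
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_TRIES):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return from_networkx(g)
    raise UsageError(
        f"no connected gnm({n}, {m}) instance in {_MAX_TRIES} draws; "
        "the requested density is too low"
    )


def pref(n: int, d: int = 2, seed=None) -> Network:
    """Preferential-attachment (scale-free) graph on ``n`` nodes.

    Bollobás linearized-chord-diagram construction: nodes arrive one at
    a time and draw ``d`` endpoints, each chosen with probability
    proportional to current degree (the arriving node's own half-edges
    included, so self-loops and duplicate pairs can occur and are
    dropped in the simple-graph cleanup).  This is the classic rigorous
    formulation of the Barabási–Albert model; it produces the heavy
    hub tail that distinguishes these ensembles from the uniform
    ``erdrey`` family.  Instances are redrawn until connected.  For
    ``d = 2`` the edge count is just under ``2n``.
    """
    if d < 1:
        raise UsageError(f"edges per new node must be >= 1, got {d}")
    if n <= d:
        raise UsageError(f"need n > d, got n={n}, d={d}")
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_TRIES):
        # each endpoint occurrence weights a node by its current degree
        chances: list[int] = []
        edges: list[tuple[int, int]] = []
        for v in range(n):
            for _ in range(d):
                chances.append(v)  # v's own half-edge joins the pool
                u = chances[rng.integers(len(chances))]
                chances.append(u)
                if u != v:
                    edges.append((u, v))
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edges)
        if nx.is_connected(g):
            return from_networkx(g)
    raise UsageError(
        f"no connected pref({n}, {d}) instance in {_MAX_TRIES} draws"
    )


def star(n: int) -> Network:
    """Star on ``n`` nodes: node 0 is the hub."""
    if n < 2:
        raise UsageError(f"need at least 2 nodes, got {n}")
    return from_networkx(nx.star_graph(n - 1))


def complete(n: int) -> Network:
    if n < 2:
        raise UsageError(f"need at least 2 nodes, got {n}")
    return from_networkx(nx.complete_graph(n))


def path(n: int) -> Network:
    if n < 2:
        raise UsageError(f"need at least 2 nodes, got {n}")
    return from_networkx(nx.path_graph(n))


def from_spec(spec: str, seed=None) -> Network:
    """Build a generator graph from a compact string spec.

    Examples: ``erdrey:n=2000,m=8000``, ``pref:n=2000,d=2``,
    ``star:n=10``.  Used by the CLI's ``--network`` flag.
    """
    name, _, argstr = spec.partition(":")
    name = name.strip().lower()
    makers = {"erdrey": erdrey, "pref": pref, "star": star,
              "complete": complete, "path": path}
    if name not in makers:
        raise UsageError(
            f"unknown generator {name!r}; expected one of {sorted(makers)}"
        )
    kwargs: dict[str, int] = {}
    if argstr.strip():
        for part in argstr.split(","):
            key, _, val = part.partition("=")
            key = key.strip()
            if not key or not val.strip():
                raise UsageError(f"malformed generator argument {part!r}")
            try:
                kwargs[key] = int(val)
            except ValueError as exc:
                raise UsageError(f"generator argument {part!r} must be an integer") from exc
    if name in ("erdrey", "pref"):
        kwargs.setdefault("seed", seed)
    try:
        return makers[name](**kwargs)
    except TypeError as exc:
        raise UsageError(f"bad arguments for generator {name!r}: {exc}") from exc
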