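"""Graph data model and standard-format I/O.

A :class:`Network` is an undirected simple graph stored as a symmetric
0/1 sparse adjacency matrix with a zero diagonal.  Node removal is
*logical*: the node's row and column are zeroed and its id is added to a
removed-set, keeping the matrix dimension fixed.  A zeroed row cannot
contribute to any walk, so walk-based centralities of the surviving
nodes are identical to those computed on the compacted induced
subgraph; the fixed dimension keeps node ids stable across an attack.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.sparse import csgraph

from .errors import GraphFormatError, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "load_matrix_market",
    "save_matrix_market",
    "load_edgelist",
    "extract_lcc",
    "remove_node",
    "distance",
    "from_networkx",
]


def _clean_adjacency(a: sp.spmatrix | np.ndarray) -> sp.csr_array:
    """Binarize, symmetrize and zero the diagonal of an adjacency matrix."""
    a = sp.csr_array(a)
    if a.shape[0] != a.shape[1]:
        raise GraphFormatError(f"adjacency matrix must be square, got {a.shape}")
    a = (a != 0).astype(np.float64)
    a = ((a + a.T) != 0).astype(np.float64)
    a.setdiag(0)
    a.eliminate_zeros()
    a = sp.csr_array(a)
    a.sort_indices()
    return a


class Network:
    """Undirected simple graph with logical node removal.

    Parameters
    ----------
    adjacency :
        Square matrix (dense or sparse).  Entries are binarized
        (any nonzero weight becomes 1), symmetrized and the diagonal is
        dropped, so any reasonable input yields a valid simple graph.
    labels :
        Optional original node identifiers, one per node.  Kept for
        reporting; all internal indexing is 0-based positional.
    """

    def __init__(
        self,
        adjacency: sp.spmatrix | np.ndarray,
        labels: Sequence | None = None,
    ) -> None:
        self._adj = _clean_adjacency(adjacency)
        n = self._adj.shape[0]
        if labels is not None and len(labels) != n:
            raise UsageError(f"{len(labels)} labels for {n} nodes")
        self.labels = list(labels) if labels is not None else None
        self._present = np.ones(n, dtype=bool)
        self._masked_cache: sp.csr_array | None = self._adj

    # -- basic properties -------------------------------------------------

    @property
    def n_total(self) -> int:
        """Node count of the original labeling (removed nodes included)."""
        return self._adj.shape[0]

    @property
    def n_present(self) -> int:
        return int(self._present.sum())

    @property
    def present_mask(self) -> np.ndarray:
        """Boolean mask over 0..n_total-1; read-only view."""
        v = self._present.view()
        v.flags.writeable = False
        return v

    @property
    def present_nodes(self) -> np.ndarray:
        return np.flatnonzero(self._present)

    @property
    def removed(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(~self._present).tolist())

    @property
    def adjacency(self) -> sp.csr_array:
        """Current adjacency: rows/columns of removed nodes are zero."""
        if self._masked_cache is None:
            d = sp.diags_array(self._present.astype(np.float64))
            m = sp.csr_array(d @ self._adj @ d)
            m.eliminate_zeros()
            m.sort_indices()
            self._masked_cache = m
        return self._masked_cache

    @property
    def degrees(self) -> np.ndarray:
        """Degree of every node in the current (masked) graph."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def is_present(self, i: int) -> bool:
        if not 0 <= i < self.n_total:
            raise UsageError(f"node id {i} out of range [0, {self.n_total})")
        return bool(self._present[i])

    def neighbors(self, i: int) -> np.ndarray:
        """Present neighbors of a present node."""
        self._require_present(i)
        a = self.adjacency
        return a.indices[a.indptr[i] : a.indptr[i + 1]].copy()

    def _require_present(self, i: int) -> None:
        if not self.is_present(i):
            raise UsageError(f"node {i} has been removed")

    # -- mutation ---------------------------------------------------------

    def remove_node(self, i: int) -> "Network":
        """Logically remove node ``i``: zero its row and column.

        Returns ``self`` for chaining.  Removing an absent node is a
        usage error.
        """
        self._require_present(i)
        self._present[i] = False
        self._masked_cache = None
        return self

    def copy(self) -> "Network":
        new = object.__new__(Network)
        new._adj = self._adj
        new.labels = None if self.labels is None else list(self.labels)
        new._present = self._present.copy()
        new._masked_cache = self._masked_cache
        return new

    # -- queries ----------------------------------------------------------

    def distance(self, i: int, j: int) -> float:
        """Shortest-path length between present nodes; ``inf`` if disconnected."""
        self._require_present(i)
        self._require_present(j)
        if i == j:
            return 0.0
        d = csgraph.shortest_path(
            self.adjacency, method="D", unweighted=True, indices=i
        )
        return float(d[j])

    def connected_components(self) -> tuple[int, np.ndarray]:
        """Component count and per-node component ids, over present nodes only."""
        ncomp, comp = csgraph.connected_components(self.adjacency, directed=False)
        comp = comp.copy()
        comp[~self._present] = -1
        # isolated present nodes are their own components; removed ones are not
        ids = np.unique(comp[self._present])
        return len(ids), comp

    def is_connected(self) -> bool:
        ncomp, _ = self.connected_components()
        return ncomp <= 1

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.present_nodes.tolist())
        a = sp.coo_array(sp.triu(self.adjacency))
        g.add_edges_from(zip(a.row.tolist(), a.col.tolist()))
        return g

    def validate(self) -> None:
        """Assert the structural invariants; raises ``AssertionError``."""
        a = self.adjacency
        assert (a != a.T).nnz == 0, "adjacency must be symmetric"
        assert a.diagonal().sum() == 0, "diagonal must be zero"
        removed = ~self._present
        if removed.any():
            rows = np.asarray(a[removed, :].sum(axis=1)).ravel()
            assert not rows.any(), "removed rows must be zero"
        assert self.n_present == self.n_total - removed.sum()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Network(n_total={self.n_total}, n_present={self.n_present}, "
            f"edges={self.n_edges})"
        )


# -- module-level operation wrappers --------------------------------------


def remove_node(g: Network, i: int) -> Network:
    """Zero row and column ``i`` of ``g`` (in place); returns ``g``."""
    return g.remove_node(i)


def distance(g: Network, i: int, j: int) -> float:
    return g.distance(i, j)


def extract_lcc(g: Network) -> Network:
    """Induced subgraph on the largest connected component.

    Ties between equally sized components are broken by the smallest
    minimum original node id, which makes the result deterministic.
    Nodes are relabeled 0..m-1; the original identifiers (labels when
    available, otherwise original indices) are kept in ``labels``.
    """
    if g.n_present == 0:
        raise UsageError("graph has no present nodes")
    _, comp = g.connected_components()
    present = g.present_nodes
    comp_ids, sizes = np.unique(comp[present], return_counts=True)
    best = None
    for cid, size in zip(comp_ids, sizes):
        min_id = int(present[comp[present] == cid].min())
        key = (-size, min_id)
        if best is None or key < best[0]:
            best = (key, cid)
    keep = present[comp[present] == best[1]]
    sub = g.adjacency[np.ix_(keep, keep)]
    labels = (
        [g.labels[i] for i in keep] if g.labels is not None else keep.tolist()
    )
    return Network(sub, labels=labels)


def from_networkx(g, nodes: Iterable | None = None) -> Network:
    """Build a Network from a networkx graph (nodes sorted by default)."""
    import networkx as nx

    nodelist = list(nodes) if nodes is not None else sorted(g.nodes())
    a = nx.to_scipy_sparse_array(g, nodelist=nodelist, format="csr", dtype=np.float64)
    return Network(a, labels=nodelist)


# -- I/O -------------------------------------------------------------------


def load_matrix_market(path) -> Network:
    """Read a Matrix Market coordinate file as an undirected simple graph.

    Both ``general`` and ``symmetric`` headers are accepted.  Weights
    are binarized, the matrix is symmetrized and self-loops dropped.
    No component extraction is performed here; see :func:`extract_lcc`.
    """
    try:
        a = mmread(path)
    except Exception as exc:  # scipy raises bare ValueError with the line
        raise GraphFormatError(f"invalid Matrix Market file {path}: {exc}") from exc
    if a.shape[0] != a.shape[1]:
        raise GraphFormatError(
            f"{path}: adjacency matrix must be square, got {a.shape}"
        )
    return Network(a)


def save_matrix_market(g: Network, path) -> None:
    """Write the current (masked) adjacency in symmetric coordinate format."""
    mmwrite(path, sp.coo_matrix(g.adjacency), symmetry="symmetric", field="integer")


def load_edgelist(path) -> Network:
    """Read a whitespace-separated edge list (``#`` starts a comment).

    Each data line holds two node tokens and an optional weight token;
    zero-weight lines and self-pairs are dropped with a warning, and
    duplicate or reversed pairs collapse to a single edge.  Node labels
    are arbitrary strings, indexed in order of first appearance.
    """
    index: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()

    def node_id(tok: str) -> int:
        if tok not in index:
            index[tok] = len(index)
        return index[tok]

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.split()
            if len(toks) not in (2, 3):
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 2 node tokens "
                    f"(plus optional weight), got {len(toks)}"
                )
            if len(toks) == 3:
                try:
                    w = float(toks[2])
                except ValueError as exc:
                    raise GraphFormatError(
                        f"{path}:{lineno}: unparseable weight {toks[2]!r}"
                    ) from exc
                if w == 0:
                    logger.warning("%s:%d: zero-weight edge dropped", path, lineno)
                    continue
            u, v = node_id(toks[0]), node_id(toks[1])
            if u == v:
                logger.warning("%s:%d: self-loop on %r dropped", path, lineno, toks[0])
                continue
            edges.add((min(u, v), max(u, v)))
    if not index:
        raise GraphFormatError(f"{path}: no nodes found")
    n = len(index)
    if edges:
        rows, cols = zip(*edges)
        a = sp.coo_array(
            (np.ones(len(edges)), (np.array(rows), np.array(cols))), shape=(n, n)
        )
    else:
        a = sp.coo_array((n, n))
    labels = [tok for tok, _ in sorted(index.items(), key=lambda kv: kv[1])]
    return Network(a, labels=labels)
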