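"""Graph data model, edge-list I/O, mesoscale patches, and thresholding.

The package works on undirected, unweighted graphs (self-edges allowed).
Node labels are opaque strings; edge lists (two whitespace-separated labels
per line, ``#`` comments) are the canonical on-disk format.

A *mesoscale patch* is the k x k adjacency matrix of the subgraph induced by
the node set of a k-path, with rows/columns ordered by the path.  Patches are
flattened column-wise (Fortran order) into length-k^2 vectors; the positions
(i, i+1) and (i+1, i) are the *on-chain* entries, everything else off the
diagonal is *off-chain*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Graph",
    "WeightedGraph",
    "Patch",
    "GraphError",
    "ParseError",
    "InvalidPathError",
    "read_edgelist",
    "write_edgelist",
    "induced_patch",
    "vectorize",
    "devectorize",
    "threshold_graph",
    "on_chain_positions",
    "patch_degrees_of_freedom",
]


class GraphError(ValueError):
    """Base error for graph-level problems."""


class ParseError(GraphError):
    """Malformed edge-list input."""


class InvalidPathError(GraphError):
    """A node sequence that is not a valid k-path of the graph."""


class Graph:
    """Undirected, unweighted graph with opaque node labels.

    Self-edges are permitted and stored like any other adjacency.  Nodes are
    kept in insertion order, which fixes a stable integer index for each
    label; samplers and generators work on these indices.
    """

    __slots__ = ("_labels", "_index", "_adj", "_n_edges", "_nbr_cache")

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[Tuple[str, str]] = (),
    ) -> None:
        self._labels: List[str] = []
        self._index: Dict[str, int] = {}
        self._adj: List[set] = []
        self._n_edges = 0
        self._nbr_cache: Optional[List[np.ndarray]] = None
        for v in nodes:
            self.add_node(v)
        for u, v in edges:
            self.add_edge(u, v)

    # -- construction -----------------------------------------------------

    def add_node(self, label: str) -> int:
        i = self._index.get(label)
        if i is None:
            i = len(self._labels)
            self._index[label] = i
            self._labels.append(label)
            self._adj.append(set())
            self._nbr_cache = None
        return i

    def add_edge(self, u: str, v: str) -> None:
        i = self.add_node(u)
        j = self.add_node(v)
        if j not in self._adj[i]:
            self._adj[i].add(j)
            self._adj[j].add(i)
            self._n_edges += 1
            self._nbr_cache = None

    @classmethod
    def from_edge_indices(
        cls, labels: Sequence[str], rows: np.ndarray, cols: np.ndarray
    ) -> "Graph":
        """Fast constructor from parallel index arrays (rows[k] -- cols[k])."""
        g = cls()
        g._labels = list(labels)
        g._index = {v: i for i, v in enumerate(g._labels)}
        g._adj = [set() for _ in g._labels]
        adj = g._adj
        n_edges = 0
        for i, j in zip(rows.tolist(), cols.tolist()):
            if j not in adj[i]:
                adj[i].add(j)
                adj[j].add(i)
                n_edges += 1
        g._n_edges = n_edges
        return g

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> List[str]:
        return list(self._labels)

    def __len__(self) -> int:
        return len(self._labels)

    def number_of_nodes(self) -> int:
        return len(self._labels)

    def number_of_edges(self) -> int:
        return self._n_edges

    def has_node(self, v: str) -> bool:
        return v in self._index

    def index_of(self, v: str) -> int:
        return self._index[v]

    def label_of(self, i: int) -> str:
        return self._labels[i]

    def has_edge(self, u: str, v: str) -> bool:
        i = self._index.get(u)
        j = self._index.get(v)
        if i is None or j is None:
            return False
        return j in self._adj[i]

    def has_edge_index(self, i: int, j: int) -> bool:
        return j in self._adj[i]

    def neighbors(self, v: str) -> List[str]:
        return [self._labels[j] for j in sorted(self._adj[self._index[v]])]

    def degree(self, v: str) -> int:
        """Node degree; a self-edge contributes 2."""
        i = self._index[v]
        return len(self._adj[i]) + (1 if i in self._adj[i] else 0)

    def edges(self) -> Iterator[Tuple[str, str]]:
        """Iterate each undirected edge once, in index order (u-index <= v-index)."""
        for i, nbrs in enumerate(self._adj):
            for j in sorted(nbrs):
                if j >= i:
                    yield (self._labels[i], self._labels[j])

    def edge_index_pairs(self) -> Iterator[Tuple[int, int]]:
        for i, nbrs in enumerate(self._adj):
            for j in nbrs:
                if j >= i:
                    yield (i, j)

    def edge_set(self) -> set:
        """Edges as a set of canonically sorted label pairs."""
        return {edge_key(u, v) for u, v in self.edges()}

    def neighbor_arrays(self) -> List[np.ndarray]:
        """Sorted neighbor-index array per node (cached; includes self-edges)."""
        if self._nbr_cache is None:
            self._nbr_cache = [
                np.array(sorted(s), dtype=np.int64) for s in self._adj
            ]
        return self._nbr_cache

    def adjacency_csr(self):
        """scipy CSR adjacency (binary; a self-edge is a single 1 on the diagonal)."""
        from scipy.sparse import csr_matrix

        nbrs = self.neighbor_arrays()
        indptr = np.zeros(len(self._adj) + 1, dtype=np.int64)
        indptr[1:] = np.cumsum([len(a) for a in nbrs])
        indices = (
            np.concatenate(nbrs) if nbrs else np.zeros(0, dtype=np.int64)
        )
        data = np.ones(len(indices), dtype=np.float64)
        n = len(self._adj)
        return csr_matrix((data, indices, indptr), shape=(n, n))

    def is_connected(self) -> bool:
        n = len(self._adj)
        if n == 0:
            return False
        seen = [False] * n
        stack = [0]
        seen[0] = True
        count = 1
        while stack:
            i = stack.pop()
            for j in self._adj[i]:
                if not seen[j]:
                    seen[j] = True
                    count += 1
                    stack.append(j)
        return count == n

    def copy(self) -> "Graph":
        g = Graph()
        g._labels = list(self._labels)
        g._index = dict(self._index)
        g._adj = [set(s) for s in self._adj]
        g._n_edges = self._n_edges
        return g

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Graph(n={len(self._labels)}, m={self._n_edges})"


def edge_key(u: str, v: str) -> Tuple[str, str]:
    """Canonical (sorted) form of an unordered node pair."""
    return (u, v) if u <= v else (v, u)


class WeightedGraph:
    """Node-pair weights in [0, 1]; absent pairs have weight 0.

    This is the container for reconstructed networks G_recons: each weight is
    the confidence that the corresponding edge is a true edge.
    """

    __slots__ = ("_labels", "weights")

    def __init__(
        self,
        nodes: Iterable[str] = (),
        weights: Optional[Dict[Tuple[str, str], float]] = None,
    ) -> None:
        self._labels = list(dict.fromkeys(nodes))
        self.weights: Dict[Tuple[str, str], float] = {}
        if weights:
            for (u, v), w in weights.items():
                self.set_weight(u, v, w)

    @property
    def nodes(self) -> List[str]:
        return list(self._labels)

    def set_weight(self, u: str, v: str, w: float) -> None:
        if not 0.0 <= w <= 1.0:
            raise GraphError(f"weight {w!r} outside [0, 1]")
        self.weights[edge_key(u, v)] = float(w)

    def weight(self, u: str, v: str) -> float:
        return self.weights.get(edge_key(u, v), 0.0)

    @classmethod
    def from_graph(cls, g: Graph) -> "WeightedGraph":
        """Binary weighting: each edge of ``g`` gets weight 1."""
        wg = cls(g.nodes)
        for u, v in g.edges():
            wg.weights[edge_key(u, v)] = 1.0
        return wg

    def __len__(self) -> int:
        return len(self._labels)


@dataclass(frozen=True)
class Patch:
    """Mesoscale patch: ordered k-path and the induced k x k adjacency matrix."""

    k: int
    matrix: np.ndarray
    path: Tuple[str, ...] = field(default=())

    def vector(self) -> np.ndarray:
        return vectorize(self.matrix)


def read_edgelist(path) -> Graph:
    """Read a whitespace-separated edge list; '#' lines are comments.

    Reversed duplicates are merged; extra columns (e.g. weights) are ignored;
    a line "a a" records a self-edge.
    """
    g = Graph()
    n_data_lines = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected at least 2 tokens, got {line!r}"
                )
            g.add_edge(tokens[0], tokens[1])
            n_data_lines += 1
    if n_data_lines == 0:
        raise ParseError(f"{path}: no edges found (empty edge list)")
    return g


def write_edgelist(g: Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in g.edges():
            fh.write(f"{u} {v}\n")


def write_weighted_edgelist(wg: WeightedGraph, path) -> None:
    """Write 'u v weight' rows with >= 6 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        for (u, v), w in sorted(wg.weights.items()):
            fh.write(f"{u} {v} {w:.6g}\n")


def induced_patch(g: Graph, path: Sequence[str]) -> Patch:
    """Patch A_x of an ordered k-path x: A_x(i, j) = adjacency of x_i, x_j.

    Raises :class:`InvalidPathError` when nodes repeat, are missing from the
    graph, or consecutive nodes are not adjacent.
    """
    k = len(path)
    if k < 2:
        raise InvalidPathError("a k-path needs k >= 2 nodes")
    if len(set(path)) != k:
        raise InvalidPathError(f"nodes in path {path!r} are not distinct")
    try:
        idx = [g.index_of(v) for v in path]
    except KeyError as exc:
        raise InvalidPathError(f"node {exc.args[0]!r} not in graph") from None
    for a in range(k - 1):
        if not g.has_edge_index(idx[a], idx[a + 1]):
            raise InvalidPathError(
                f"consecutive nodes {path[a]!r}, {path[a + 1]!r} are not adjacent"
            )
    m = np.zeros((k, k), dtype=np.uint8)
    for a in range(k):
        ia = idx[a]
        for b in range(a, k):
            if g.has_edge_index(ia, idx[b]):
                m[a, b] = 1
                m[b, a] = 1
    return Patch(k=k, matrix=m, path=tuple(path))


def patch_matrix_from_indices(g: Graph, idx: Sequence[int]) -> np.ndarray:
    """Patch matrix for a path given as node indices (no validity checks)."""
    k = len(idx)
    m = np.zeros((k, k), dtype=np.float64)
    adj = g._adj  # internal fast path used by ndl/ndr
    for a in range(k):
        ia = idx[a]
        row = adj[ia]
        for b in range(a, k):
            if idx[b] in row:
                m[a, b] = 1.0
                m[b, a] = 1.0
    return m


def vectorize(m: np.ndarray) -> np.ndarray:
    """Column-wise flatten: the second column goes underneath the first."""
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise GraphError(f"expected a square matrix, got shape {m.shape}")
    return m.reshape(-1, order="F")


def devectorize(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize`."""
    v = np.asarray(v).ravel()
    k = math.isqrt(v.size)
    if k * k != v.size:
        raise GraphError(f"vector length {v.size} is not a perfect square")
    return v.reshape((k, k), order="F")


def threshold_graph(wg: WeightedGraph, theta: float) -> Graph:
    """Binary graph keeping pairs with weight strictly greater than theta."""
    if not 0.0 <= theta <= 1.0:
        raise GraphError(f"theta {theta!r} outside [0, 1]")
    g = Graph(nodes=wg.nodes)
    for (u, v), w in wg.weights.items():
        if w > theta:
            g.add_edge(u, v)
    return g


def on_chain_positions(k: int) -> np.ndarray:
    """Boolean k x k mask of on-chain positions (i, i+1) and (i+1, i)."""
    mask = np.zeros((k, k), dtype=bool)
    idx = np.arange(k - 1)
    mask[idx, idx + 1] = True
    mask[idx + 1, idx] = True
    return mask


def coding_positions(k: int, mask_on_chain: bool = False) -> np.ndarray:
    """Flat (column-wise) indices of patch entries that participate in coding.

    The diagonal is always excluded; with ``mask_on_chain`` the 2(k-1)
    on-chain entries are excluded as well.
    """
    keep = ~np.eye(k, dtype=bool)
    if mask_on_chain:
        keep &= ~on_chain_positions(k)
    return np.nonzero(keep.reshape(-1, order="F"))[0]


def patch_degrees_of_freedom(k: int) -> int:
    """Number of free off-diagonal, off-chain degrees of freedom of a patch.

    A symmetric binary k x k patch has C(k, 2) unordered off-diagonal pairs;
    the k - 1 on-chain pairs are fixed at 1 by path validity, leaving
    C(k, 2) - (k - 1) free pairs.
    """
    if k < 2:
        raise GraphError("k must be >= 2")
    return math.comb(k, 2) - (k - 1)
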