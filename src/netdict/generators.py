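"""Random-graph generators and corruption models with ground-truth labels.

Generators: Erdős–Rényi G(n, p); Watts–Strogatz ring-rewiring (either end of
a rewired edge is detached with equal probability and reattached uniformly,
redrawing on self-loop/duplicate collisions, so the edge count n*k/2 is
conserved); Barabási–Albert linear preferential attachment grown from n0
isolated nodes (n0 * (n - n0) edges); and a stochastic block model with an
arbitrary symmetric block-probability matrix, which specializes to ER for a
single block.

Corruption models for denoising experiments:

* -ER (subtractive): keep a uniformly random spanning tree (Wilson's
  loop-erased-random-walk sampler) and delete floor(|E_0| / 2) of the
  off-tree edges uniformly at random; the observed graph stays connected.
* +ER (additive): either exactly floor(|E| / 2) uniformly random nonedges
  ("uniform" variant) or, in the "block" variant, pick 5% of the nodes and
  add each absent pair among them independently with probability 0.3.
* +WS (additive): plant a Watts–Strogatz graph on n0 randomly chosen nodes;
  the planted edge set has exactly n0 * floor(k/2) edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .graph_core import Graph, GraphError, edge_key

__all__ = [
    "CorruptionRecord",
    "er_graph",
    "ws_graph",
    "ba_graph",
    "sbm_graph",
    "path_graph",
    "uniform_spanning_tree",
    "corrupt_subtract_er",
    "corrupt_add_er",
    "corrupt_add_ws",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class CorruptionRecord:
    """Observed graph plus ground truth of what was added or removed."""

    observed: Graph
    truth: Graph
    added_edges: Set[Tuple[str, str]]
    removed_edges: Set[Tuple[str, str]]
    noise_type: str
    params: Dict = field(default_factory=dict)


# -- generators -----------------------------------------------------------


def path_graph(n: int) -> Graph:
    """Simple path on nodes '0' ... 'n-1' (test fixture staple)."""
    g = Graph(nodes=(str(i) for i in range(n)))
    for i in range(n - 1):
        g.add_edge(str(i), str(i + 1))
    return g


def _bernoulli_pairs(
    n_pairs: int, p: float, rng: np.random.Generator, chunk: int = 4_000_000
) -> np.ndarray:
    """Indices of successes among n_pairs independent Bernoulli(p) trials."""
    hits = []
    for start in range(0, n_pairs, chunk):
        m = min(chunk, n_pairs - start)
        mask = rng.random(m) < p
        hits.append(np.nonzero(mask)[0] + start)
    return np.concatenate(hits) if hits else np.zeros(0, dtype=np.int64)


def _triu_unrank(idx: np.ndarray, n: int) -> Tuple[np.ndarray, np.ndarray]:
    """Map linear indices of the strict upper triangle of an n x n matrix to
    (row, col) with row < col, ordered row-major."""
    # row i occupies indices [i*n - i*(i+1)/2 - i, ...); invert by solving
    # the quadratic for the row.
    idx = idx.astype(np.float64)
    b = 2 * n - 1
    i = np.floor((b - np.sqrt(b * b - 8 * idx)) / 2).astype(np.int64)
    offset = i * (2 * n - i - 1) // 2
    j = (idx.astype(np.int64) - offset) + i + 1
    return i, j


def er_graph(n: int, p: float, seed=None) -> Graph:
    """Erdős–Rényi G(n, p): each distinct pair is an edge independently
    with probability p; no self-edges."""
    if n < 1:
        raise GraphError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise GraphError("p must lie in [0, 1]")
    rng = _as_rng(seed)
    n_pairs = n * (n - 1) // 2
    hits = _bernoulli_pairs(n_pairs, p, rng)
    rows, cols = _triu_unrank(hits, n)
    labels = [str(i) for i in range(n)]
    return Graph.from_edge_indices(labels, rows, cols)


def ws_graph(n: int, k: int, p: float, seed=None) -> Graph:
    """Watts–Strogatz small-world graph with conserved edge count n*k/2.

    Start from a ring where each node is adjacent to its k nearest
    neighbors; each edge is independently rewired with probability p by
    detaching one of its two ends (chosen with equal probability) and
    reattaching it to a uniformly random node, redrawing on self-loops and
    duplicates.
    """
    if k % 2 != 0:
        raise GraphError("k must be even")
    if not 0 < k < n:
        raise GraphError("need 0 < k < n")
    if not 0.0 <= p <= 1.0:
        raise GraphError("p must lie in [0, 1]")
    rng = _as_rng(seed)
    edges: List[Tuple[int, int]] = []
    edge_set: Set[Tuple[int, int]] = set()
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            e = (i, j) if i < j else (j, i)
            if e not in edge_set:
                edge_set.add(e)
                edges.append(e)
    for pos, (u, v) in enumerate(edges):
        if rng.random() >= p:
            continue
        keep = u if rng.random() < 0.5 else v  # detach the other end
        edge_set.discard((u, v) if u < v else (v, u))
        while True:
            w = int(rng.integers(0, n))
            if w == keep:
                continue
            e = (keep, w) if keep < w else (w, keep)
            if e in edge_set:
                continue
            edge_set.add(e)
            edges[pos] = e
            break
    labels = [str(i) for i in range(n)]
    rows = np.array([e[0] for e in edges], dtype=np.int64)
    cols = np.array([e[1] for e in edges], dtype=np.int64)
    return Graph.from_edge_indices(labels, rows, cols)


def ba_graph(n: int, n0: int, seed=None) -> Graph:
    """Barabási–Albert preferential attachment from n0 isolated seed nodes.

    Each arriving node attaches n0 distinct edges with probability
    proportional to current degree; the first arrival attaches uniformly
    (all seed degrees are 0).  The final graph has n0 * (n - n0) edges.
    """
    if not 1 <= n0 < n:
        raise GraphError("need 1 <= n0 < n")
    rng = _as_rng(seed)
    g = Graph(nodes=(str(i) for i in range(n)))
    # multiset of edge endpoints: drawing from it is degree-proportional
    repeated: List[int] = []
    targets: Set[int] = set(range(n0))  # first node joins all n0 seeds
    for new in range(n0, n):
        for t in targets:
            g.add_edge(str(new), str(t))
            repeated.append(new)
            repeated.append(t)
        targets = set()
        while len(targets) < n0 and new + 1 < n:
            targets.add(repeated[int(rng.integers(0, len(repeated)))])
    return g


def sbm_graph(
    community_sizes: Sequence[int], B: np.ndarray, seed=None
) -> Graph:
    """Stochastic block model: nodes split into blocks C_1, ..., C_k0;
    pair {x, y} is an edge independently with probability B[block(x), block(y)].

    With a single block this is exactly ER(n, B[0, 0]).
    """
    B = np.asarray(B, dtype=np.float64)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise GraphError("B must be square")
    if not np.allclose(B, B.T):
        raise GraphError("B must be symmetric")
    if B.min() < 0 or B.max() > 1:
        raise GraphError("entries of B must lie in [0, 1]")
    if len(community_sizes) != B.shape[0]:
        raise GraphError("community_sizes length must match B")
    rng = _as_rng(seed)
    offsets = np.concatenate([[0], np.cumsum(community_sizes)])
    n = int(offsets[-1])
    all_rows: List[np.ndarray] = []
    all_cols: List[np.ndarray] = []
    k0 = len(community_sizes)
    for a in range(k0):
        for b in range(a, k0):
            na, nb = community_sizes[a], community_sizes[b]
            p = float(B[a, b])
            if p == 0.0:
                continue
            if a == b:
                n_pairs = na * (na - 1) // 2
                hits = _bernoulli_pairs(n_pairs, p, rng)
                i, j = _triu_unrank(hits, na)
            else:
                n_pairs = na * nb
                hits = _bernoulli_pairs(n_pairs, p, rng)
                i, j = hits // nb, hits % nb
            all_rows.append(i + offsets[a])
            all_cols.append(j + offsets[b])
    labels = [str(i) for i in range(n)]
    rows = np.concatenate(all_rows) if all_rows else np.zeros(0, dtype=np.int64)
    cols = np.concatenate(all_cols) if all_cols else np.zeros(0, dtype=np.int64)
    return Graph.from_edge_indices(labels, rows.astype(np.int64), cols.astype(np.int64))


# -- corruption models ----------------------------------------------------


def uniform_spanning_tree(g: Graph, seed=None) -> Set[Tuple[str, str]]:
    """Uniformly random spanning tree via Wilson's loop-erased random walk."""
    if not g.is_connected():
        raise GraphError("graph must be connected")
    rng = _as_rng(seed)
    n = len(g)
    nbrs = g.neighbor_arrays()
    in_tree = [False] * n
    nxt = [-1] * n
    root = int(rng.integers(0, n))
    in_tree[root] = True
    for start in range(n):
        if in_tree[start]:
            continue
        # random walk from start until hitting the tree, recording successors
        u = start
        while not in_tree[u]:
            choices = nbrs[u]
            nxt[u] = int(choices[int(rng.integers(0, len(choices)))])
            u = nxt[u]
        # loop erasure: retrace the successor pointers
        u = start
        while not in_tree[u]:
            in_tree[u] = True
            u = nxt[u]
    # overwriting nxt[] on revisits performs the loop erasure, so the final
    # successor pointers of the non-root nodes are exactly the tree edges
    labels = g.nodes
    return {edge_key(labels[v], labels[nxt[v]]) for v in range(n) if v != root}


def corrupt_subtract_er(g: Graph, seed=None) -> CorruptionRecord:
    """-ER noise: delete floor(|E_0|/2) uniformly random off-tree edges,
    where E_0 is the complement of a uniformly random spanning tree."""
    rng = _as_rng(seed)
    tree = uniform_spanning_tree(g, rng)
    e0 = sorted(g.edge_set() - tree)
    n_remove = len(e0) // 2
    removed: Set[Tuple[str, str]] = set()
    if n_remove:
        idx = rng.choice(len(e0), size=n_remove, replace=False)
        removed = {e0[i] for i in idx}
    observed = Graph(nodes=g.nodes)
    for u, v in g.edges():
        if edge_key(u, v) not in removed:
            observed.add_edge(u, v)
    return CorruptionRecord(
        observed=observed,
        truth=g.copy(),
        added_edges=set(),
        removed_edges=removed,
        noise_type="-ER",
        params={"n_removed": n_remove, "n_off_tree": len(e0)},
    )


def corrupt_add_er(
    g: Graph,
    variant: str = "uniform",
    seed=None,
    q_nodes: float = 0.05,
    q_p: float = 0.3,
) -> CorruptionRecord:
    """+ER noise.  'uniform': exactly floor(|E|/2) uniformly random
    nonadjacent pairs become false edges.  'block': ceil(q_nodes * |V|)
    random nodes, each absent pair among them added with probability q_p."""
    rng = _as_rng(seed)
    labels = g.nodes
    n = len(labels)
    added: Set[Tuple[str, str]] = set()
    if variant == "uniform":
        target = g.number_of_edges() // 2
        n_pairs = n * (n - 1) // 2
        n_nonedges = n_pairs - len([1 for u, v in g.edges() if u != v])
        if n_nonedges < target:
            raise GraphError(
                f"only {n_nonedges} nonedges available, need {target}"
            )
        while len(added) < target:
            i = int(rng.integers(0, n))
            j = int(rng.integers(0, n))
            if i == j:
                continue
            u, v = labels[i], labels[j]
            key = edge_key(u, v)
            if g.has_edge(u, v) or key in added:
                continue
            added.add(key)
    elif variant == "block":
        n_sel = math.ceil(q_nodes * n)
        sel = rng.choice(n, size=n_sel, replace=False)
        for ai in range(n_sel):
            for bi in range(ai + 1, n_sel):
                u, v = labels[int(sel[ai])], labels[int(sel[bi])]
                if not g.has_edge(u, v) and rng.random() < q_p:
                    added.add(edge_key(u, v))
    else:
        raise GraphError(f"unknown +ER variant {variant!r}")
    observed = g.copy()
    for u, v in added:
        observed.add_edge(u, v)
    return CorruptionRecord(
        observed=observed,
        truth=g.copy(),
        added_edges=added,
        removed_edges=set(),
        noise_type=f"+ER-{variant}",
        params={"variant": variant, "n_added": len(added)},
    )


def corrupt_add_ws(
    g: Graph, n0: int, k: int, p: float, seed=None
) -> CorruptionRecord:
    """+WS noise: plant WS(n0, k, p) on n0 uniformly chosen nodes.

    The planted set E_3 has exactly n0 * floor(k/2) edges; planted edges
    already present in g are logged in ``params['n_collisions']`` and
    excluded from the positive-label (added) set.
    """
    if n0 > len(g):
        raise GraphError("n0 exceeds the number of nodes")
    rng = _as_rng(seed)
    labels = g.nodes
    chosen = rng.choice(len(labels), size=n0, replace=False)
    h = ws_graph(n0, k, p, rng)
    e3 = {
        edge_key(labels[int(chosen[int(a)])], labels[int(chosen[int(b)])])
        for a, b in h.edges()
    }
    added = {e for e in e3 if not g.has_edge(*e)}
    observed = g.copy()
    for u, v in e3:
        observed.add_edge(u, v)
    return CorruptionRecord(
        observed=observed,
        truth=g.copy(),
        added_edges=added,
        removed_edges=set(),
        noise_type="+WS",
        params={
            "n0": n0,
            "k": k,
            "p": p,
            "n_generated": len(e3),
            "n_collisions": len(e3) - len(added),
        },
    )
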