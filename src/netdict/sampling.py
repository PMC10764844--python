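"""Exact uniform sampling of k-walks and k-paths.

A k-walk is a node sequence (x_1, ..., x_k) with consecutive nodes adjacent;
a k-path is a k-walk with all nodes distinct.  The number of j-step walk
extensions from each node satisfies the recursion

    w_0(v) = 1,    w_j(v) = sum over u adjacent to v of w_{j-1}(u),

so the total number of k-walks is sum_v w_{k-1}(v).  Sampling the start node
proportionally to w_{k-1} and each subsequent node among the current node's
neighbors proportionally to the remaining extension counts draws a k-walk
exactly uniformly at random.  Rejecting walks with repeated nodes then yields
exactly uniform k-paths — the same target distribution as MCMC walk sampling
with rejection, but with zero mixing error.

Counts are held in float64: they can exceed 2^63 for large k on dense
graphs, and only their ratios matter for sampling.  On small graphs the
counts are exact integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .graph_core import Graph, GraphError

__all__ = [
    "WalkCountTable",
    "SamplingError",
    "build_walk_counts",
    "PathSampler",
    "sample_k_walk",
    "sample_k_path",
    "enumerate_k_walks",
    "enumerate_k_paths",
]

DEFAULT_MAX_REJECTIONS = 1_000_000


class SamplingError(GraphError):
    """No admissible sample exists, or the rejection cap was exceeded."""


@dataclass
class WalkCountTable:
    """w_j(v) for j in {0, ..., k-1}; ``counts[j, v]`` = extensions of length j."""

    k: int
    counts: np.ndarray  # shape (k, n), float64

    @property
    def total(self) -> float:
        """Total number of k-walks in the graph."""
        return float(self.counts[self.k - 1].sum())


def build_walk_counts(g: Graph, k: int) -> WalkCountTable:
    if k < 2:
        raise GraphError(f"k must be >= 2, got {k}")
    n = len(g)
    A = g.adjacency_csr()
    counts = np.zeros((k, n), dtype=np.float64)
    counts[0] = 1.0
    for j in range(1, k):
        counts[j] = A @ counts[j - 1]
    return WalkCountTable(k=k, counts=counts)


class PathSampler:
    """Reusable sampler for uniform k-walks/k-paths on a fixed graph.

    Precomputes, for every node and remaining-step count, the cumulative
    neighbor weights used in the sequential draw; one instance amortizes this
    O(k |E|) setup across many samples (minibatch learning, reconstruction).
    """

    def __init__(self, g: Graph, k: int) -> None:
        self.g = g
        self.k = k
        self.table = build_walk_counts(g, k)
        if self.table.total <= 0:
            raise SamplingError(f"graph admits no {k}-walk")
        nbrs = g.neighbor_arrays()
        self._nbrs = nbrs
        # start-node CDF over w_{k-1}
        start = self.table.counts[k - 1]
        self._start_cdf = np.cumsum(start)
        self._start_cdf /= self._start_cdf[-1]
        # per-(remaining j, node) neighbor CDFs, j = k-2 down to 0;
        # step t (1-based position t+1) uses j = k - 2 - ... see sample_walk
        self._step_cdf: List[List[Optional[np.ndarray]]] = []
        for j in range(k - 1):
            wj = self.table.counts[j]
            row: List[Optional[np.ndarray]] = []
            for v in range(len(g)):
                wts = wj[nbrs[v]]
                s = wts.sum()
                if s <= 0:
                    row.append(None)
                else:
                    c = np.cumsum(wts)
                    c /= c[-1]
                    row.append(c)
            self._step_cdf.append(row)
        self.n_rejected = 0
        self.n_accepted = 0

    def sample_walk(self, rng: np.random.Generator) -> Tuple[int, ...]:
        """One exactly uniform k-walk, as node indices."""
        k = self.k
        u = rng.random()
        v = int(np.searchsorted(self._start_cdf, u, side="right"))
        walk = [v]
        for t in range(1, k):
            j = k - 1 - t  # remaining steps after this one
            cdf = self._step_cdf[j][v]
            if cdf is None:  # pragma: no cover - unreachable from a valid start
                raise SamplingError("walk ran into a node with no extension")
            r = rng.random()
            pos = int(np.searchsorted(cdf, r, side="right"))
            v = int(self._nbrs[v][min(pos, len(cdf) - 1)])
            walk.append(v)
        return tuple(walk)

    def sample_path(
        self,
        rng: np.random.Generator,
        max_rejections: int = DEFAULT_MAX_REJECTIONS,
    ) -> Tuple[int, ...]:
        """One exactly uniform k-path (rejection over uniform k-walks)."""
        k = self.k
        rejections = 0
        while True:
            walk = self.sample_walk(rng)
            if len(set(walk)) == k:
                self.n_accepted += 1
                return walk
            rejections += 1
            self.n_rejected += 1
            if rejections > max_rejections:
                rate = self.acceptance_rate
                raise SamplingError(
                    f"exceeded {max_rejections} rejections sampling a {k}-path "
                    f"(acceptance rate so far ~{rate:.2e}); try a smaller k"
                )

    def sample_paths(
        self,
        n: int,
        rng: np.random.Generator,
        max_rejections: int = DEFAULT_MAX_REJECTIONS,
    ) -> List[Tuple[int, ...]]:
        return [self.sample_path(rng, max_rejections) for _ in range(n)]

    @property
    def acceptance_rate(self) -> float:
        tot = self.n_accepted + self.n_rejected
        return self.n_accepted / tot if tot else float("nan")


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_k_walk(g: Graph, k: int, rng) -> Tuple[str, ...]:
    """One uniformly random k-walk, as node labels."""
    sampler = PathSampler(g, k)
    walk = sampler.sample_walk(_as_rng(rng))
    return tuple(g.label_of(i) for i in walk)


def sample_k_path(
    g: Graph,
    k: int,
    rng,
    max_rejections: int = DEFAULT_MAX_REJECTIONS,
) -> Tuple[str, ...]:
    """One uniformly random k-path, as node labels."""
    sampler = PathSampler(g, k)
    path = sampler.sample_path(_as_rng(rng), max_rejections)
    return tuple(g.label_of(i) for i in path)


def enumerate_k_walks(g: Graph, k: int) -> List[Tuple[str, ...]]:
    """All k-walks by brute force (test oracle; small graphs only)."""
    if k < 2:
        raise GraphError("k must be >= 2")
    nbrs = g.neighbor_arrays()
    walks: List[Tuple[int, ...]] = []

    def extend(prefix: List[int]) -> None:
        if len(prefix) == k:
            walks.append(tuple(prefix))
            return
        for j in nbrs[prefix[-1]]:
            prefix.append(int(j))
            extend(prefix)
            prefix.pop()

    for v in range(len(g)):
        extend([v])
    return [tuple(g.label_of(i) for i in w) for w in walks]


def enumerate_k_paths(
    g: Graph, k: int, cap: int = 1_000_000
) -> List[Tuple[str, ...]]:
    """All k-paths by depth-first extension, refusing beyond ``cap`` paths."""
    if k < 2:
        raise GraphError("k must be >= 2")
    nbrs = g.neighbor_arrays()
    paths: List[Tuple[int, ...]] = []

    def extend(prefix: List[int], seen: set) -> None:
        if len(prefix) == k:
            if len(paths) >= cap:
                raise SamplingError(
                    f"more than {cap} {k}-paths; refusing to enumerate"
                )
            paths.append(tuple(prefix))
            return
        for j in nbrs[prefix[-1]]:
            j = int(j)
            if j not in seen:
                prefix.append(j)
                seen.add(j)
                extend(prefix, seen)
                seen.discard(j)
                prefix.pop()

    for v in range(len(g)):
        extend([v], {v})
    return [tuple(g.label_of(i) for i in p) for p in paths]
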