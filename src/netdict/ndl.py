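"""Network dictionary learning (NDL) via online nonnegative matrix factorization.

A *latent motif* is a k-node weighted network whose edge weights lie in
[0, 1]; r of them, stored column-wise-vectorized as a k^2 x r matrix W, form
a *network dictionary*.  NDL streams minibatches of vectorized mesoscale
patches X_t (sampled with uniform k-paths), sparse-codes each minibatch
against the current dictionary, and updates W by minimizing the usual online
matrix-factorization surrogate

    tr(W^T W P_t) - 2 tr(W^T Q_t),

where P_t and Q_t are running (1/t-weighted) aggregates of the code second
moments H H^T / N and the data-code cross moments X H^T / N.  Each column of
W is updated by projected block coordinate descent onto [0, 1]^(k^2), which
enforces the latent-motif weight range and never increases the surrogate.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph_core import (
    Graph,
    GraphError,
    devectorize,
    on_chain_positions,
    patch_matrix_from_indices,
    vectorize,
)
from .sampling import PathSampler

__all__ = [
    "NetworkDictionary",
    "AggregateStats",
    "code_patches",
    "update_dictionary",
    "learn_dictionary",
    "remove_on_chain",
    "motif_communities",
    "chain_dictionary",
]

logger = logging.getLogger(__name__)


@dataclass
class NetworkDictionary:
    """k^2 x r nonnegative dictionary whose columns are vectorized latent motifs."""

    k: int
    r: int
    W: np.ndarray
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.shape != (self.k * self.k, self.r):
            raise GraphError(
                f"dictionary shape {self.W.shape} != ({self.k ** 2}, {self.r})"
            )
        if self.W.min() < -1e-12 or self.W.max() > 1 + 1e-12:
            raise GraphError("dictionary entries must lie in [0, 1]")

    def motif(self, i: int) -> np.ndarray:
        """Latent motif L_{i+1} as a k x k weighted adjacency matrix."""
        return devectorize(self.W[:, i])

    def motifs(self) -> List[np.ndarray]:
        return [self.motif(i) for i in range(self.r)]

    def save(self, path) -> None:
        payload = {
            "k": self.k,
            "r": self.r,
            "W": self.W.tolist(),
            "meta": self.meta,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "NetworkDictionary":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            k=payload["k"],
            r=payload["r"],
            W=np.array(payload["W"], dtype=np.float64),
            meta=payload.get("meta", {}),
        )


@dataclass
class AggregateStats:
    """Sufficient statistics of the online NMF surrogate."""

    P: np.ndarray  # r x r code second-moment aggregate
    Q: np.ndarray  # k^2 x r data-code cross aggregate
    t: int = 0


def code_patches(
    X: np.ndarray,
    W: np.ndarray,
    lam: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> np.ndarray:
    """Nonnegative sparse coding: each column h_j of H minimizes
    ||X_j - W h||_2^2 + lam * ||h||_1 over h >= 0.

    Solved by cyclic coordinate descent on the (convex) quadratic, vectorized
    across columns; iterates until the largest coordinate update is below
    ``tol``.
    """
    X = np.asarray(X, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != W.shape[0]:
        raise GraphError(
            f"dimension mismatch: X has {X.shape[0]} rows, W has {W.shape[0]}"
        )
    if lam < 0:
        raise GraphError("lambda must be nonnegative")
    r, n = W.shape[1], X.shape[1]
    G = W.T @ W  # r x r Gram
    C = W.T @ X  # r x n
    H = np.zeros((r, n), dtype=np.float64)
    diag = np.diag(G).copy()
    active = diag > 1e-15  # all-zero atoms stay uncoded
    for _ in range(max_iter):
        delta = 0.0
        for i in range(r):
            if not active[i]:
                continue
            grad = G[i] @ H - C[i] + 0.5 * lam
            new = np.maximum(0.0, H[i] - grad / diag[i])
            delta = max(delta, float(np.abs(new - H[i]).max(initial=0.0)))
            H[i] = new
        if delta < tol:
            break
    return H


def update_dictionary(
    W: np.ndarray,
    stats: AggregateStats,
    n_passes: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """Minimize tr(W^T W P) - 2 tr(W^T Q) by per-column projected updates.

    Each column W_j moves by the exact minimizer of the surrogate in that
    block, W_j <- Proj_[0,1]( W_j - (W P_j - Q_j) / P_jj ); columns whose
    motif went unused this round (P_jj = 0) are skipped with a warning.
    """
    if stats.t < 1:
        raise GraphError("aggregate statistics are empty (t = 0)")
    P, Q = stats.P, stats.Q
    W = np.array(W, dtype=np.float64, copy=True)
    r = W.shape[1]
    diag = np.diag(P)
    for _ in range(n_passes):
        delta = 0.0
        for j in range(r):
            if diag[j] <= 1e-15:
                warnings.warn(
                    f"motif {j} unused in this round (P[{j},{j}] = 0); skipping",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            grad = W @ P[:, j] - Q[:, j]
            new = np.clip(W[:, j] - grad / diag[j], 0.0, 1.0)
            delta = max(delta, float(np.abs(new - W[:, j]).max(initial=0.0)))
            W[:, j] = new
        if delta < tol:
            break
    return W


def surrogate_objective(W: np.ndarray, stats: AggregateStats) -> float:
    """The online-NMF surrogate value tr(W^T W P) - 2 tr(W^T Q)."""
    return float(np.trace(W.T @ W @ stats.P) - 2.0 * np.trace(W.T @ stats.Q))


def patches_matrix(g: Graph, paths: Sequence[Tuple[int, ...]]) -> np.ndarray:
    """Stack vectorized patches of index-paths into a k^2 x n data matrix."""
    cols = [
        patch_matrix_from_indices(g, p).reshape(-1, order="F") for p in paths
    ]
    return np.stack(cols, axis=1)


def learn_dictionary(
    g: Graph,
    k: int,
    r: int,
    T: int = 100,
    N: int = 1000,
    lam: float = 0.0,
    seed: Optional[int] = None,
    max_rejections: int = 1_000_000,
    sampler: Optional[PathSampler] = None,
) -> NetworkDictionary:
    """Learn r latent motifs at scale k from T minibatches of N patches.

    The dictionary is initialized i.i.d. uniform on [0, 1] from ``seed``;
    the same seed and inputs reproduce W_T bitwise.
    """
    if T < 1 or N < 1:
        raise GraphError("T and N must be >= 1")
    rng = np.random.default_rng(seed)
    if sampler is None:
        sampler = PathSampler(g, k)
    d = k * k
    W = rng.random((d, r))
    stats = AggregateStats(P=np.zeros((r, r)), Q=np.zeros((d, r)), t=0)
    for t in range(1, T + 1):
        paths = sampler.sample_paths(N, rng, max_rejections)
        X = patches_matrix(g, paths)
        H = code_patches(X, W, lam)
        wt = 1.0 / t
        stats.P = (1 - wt) * stats.P + wt * (H @ H.T) / N
        stats.Q = (1 - wt) * stats.Q + wt * (X @ H.T) / N
        stats.t = t
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            W = update_dictionary(W, stats)
        # an atom collapsing to zero can never be coded again; reseed it
        dead = ~W.any(axis=0)
        if dead.any():
            W[:, dead] = X[:, rng.integers(0, X.shape[1], int(dead.sum()))]
    meta = {
        "seed": seed,
        "N": N,
        "T": T,
        "lambda": lam,
        "n_nodes": len(g),
        "n_edges": g.number_of_edges(),
        "acceptance_rate": sampler.acceptance_rate,
    }
    return NetworkDictionary(k=k, r=r, W=W, meta=meta)


def remove_on_chain(nd: NetworkDictionary) -> NetworkDictionary:
    """Dictionary W-bar: zero the on-chain entries of every latent motif."""
    mask = on_chain_positions(nd.k).reshape(-1, order="F")
    W = nd.W.copy()
    W[mask, :] = 0.0
    meta = dict(nd.meta)
    meta["on_chain_removed"] = True
    return NetworkDictionary(k=nd.k, r=nd.r, W=W, meta=meta)


def chain_dictionary(k: int) -> NetworkDictionary:
    """Single-motif dictionary whose motif is the k-path itself (on-chain 1s)."""
    m = on_chain_positions(k).astype(np.float64)
    return NetworkDictionary(
        k=k, r=1, W=vectorize(m)[:, None], meta={"chain": True}
    )


def motif_communities(
    motif: np.ndarray, edge_threshold: float
) -> List[int]:
    """Connected-component sizes of a motif's thresholded off-chain graph.

    Binarizes the (symmetrized) motif at ``edge_threshold``, drops on-chain
    and diagonal entries, and returns the sorted component sizes — a
    descriptive diagnostic of hubs/communities inside a latent motif.
    """
    if not 0.0 <= edge_threshold <= 1.0:
        raise GraphError("edge_threshold must lie in [0, 1]")
    m = np.asarray(motif, dtype=np.float64)
    k = m.shape[0]
    sym = (m + m.T) / 2.0
    adj = sym > edge_threshold
    adj &= ~on_chain_positions(k)
    np.fill_diagonal(adj, False)
    # union-find over k nodes
    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(k):
        for j in range(i + 1, k):
            if adj[i, j]:
                parent[find(i)] = find(j)
    sizes: Dict[int, int] = {}
    for i in range(k):
        root = find(i)
        sizes[root] = sizes.get(root, 0) + 1
    return sorted(sizes.values(), reverse=True)
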