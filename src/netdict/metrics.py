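"""Accuracy and diagnostic metrics for reconstructed networks.

The reconstruction-accuracy measure is the Jaccard index of edge sets,
|E1 ∩ E2| / |E1 ∪ E2|; its weighted generalization over node pairs,
1 - sum(min(w1, w2)) / sum(max(w1, w2)), reduces to 1 minus the binary
index on {0, 1} weights and is the distance bounded by the patch-coding
error (see :func:`netdict.ndr.reconstruction_error_bound`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, Set, Tuple

from .graph_core import Graph, WeightedGraph, edge_key

__all__ = [
    "AccuracyReport",
    "jaccard_index",
    "weighted_jaccard_distance",
    "rand_index",
    "mean_local_clustering",
    "degree_histogram",
    "accuracy_report",
]

EdgeSet = Set[Tuple[str, str]]


def _canonical(edges: Iterable[Tuple[str, str]]) -> EdgeSet:
    return {edge_key(u, v) for u, v in edges}


def jaccard_index(e1: Iterable[Tuple[str, str]], e2: Iterable[Tuple[str, str]]) -> float:
    """|e1 ∩ e2| / |e1 ∪ e2|; defined as 1 when both sets are empty."""
    s1, s2 = _canonical(e1), _canonical(e2)
    union = s1 | s2
    if not union:
        return 1.0
    return len(s1 & s2) / len(union)


def weighted_jaccard_distance(w1: WeightedGraph, w2: WeightedGraph) -> float:
    """1 - sum(min)/sum(max) over node pairs; 0 when both graphs are all-zero."""
    keys = set(w1.weights) | set(w2.weights)
    num = 0.0
    den = 0.0
    for key in keys:
        a = w1.weights.get(key, 0.0)
        b = w2.weights.get(key, 0.0)
        num += min(a, b)
        den += max(a, b)
    if den == 0.0:
        return 0.0
    return 1.0 - num / den


def rand_index(
    e1: Iterable[Tuple[str, str]],
    e2: Iterable[Tuple[str, str]],
    nodes: Iterable[str],
) -> float:
    """Fraction of unordered node pairs on which the edge indicators agree."""
    labels = list(dict.fromkeys(nodes))
    n = len(labels)
    total = n * (n - 1) // 2
    if total == 0:
        return 1.0
    s1, s2 = _canonical(e1), _canonical(e2)
    # pairs in exactly one set disagree; everything else agrees
    disagreements = len(s1 ^ s2)
    return (total - disagreements) / total


def mean_local_clustering(g: Graph) -> float:
    """Mean over nodes of 2 * (triangles through the node) / (deg * (deg - 1)).

    Self-edges are ignored; nodes of degree < 2 contribute 0.
    """
    n = len(g)
    if n == 0:
        return 0.0
    adj = [set(s) for s in g._adj]
    for i, s in enumerate(adj):
        s.discard(i)
    total = 0.0
    for i in range(n):
        nbrs = adj[i]
        d = len(nbrs)
        if d < 2:
            continue
        links = 0
        for j in nbrs:
            links += len(adj[j] & nbrs)
        # each neighbor-neighbor link counted twice in the loop above
        total += links / (d * (d - 1))
    return total / n


def degree_histogram(g: Graph) -> Dict[int, int]:
    """Counts of node degrees; a self-edge adds 2 to its node's degree."""
    return dict(Counter(g.degree(v) for v in g.nodes))


@dataclass
class AccuracyReport:
    """Edge-set agreement between an original and a reconstructed network."""

    jaccard_index: float
    rand_index: float
    theta: float
    n_original: int
    n_reconstructed: int
    n_intersection: int
    n_union: int


def accuracy_report(
    original: Graph, reconstructed: Graph, theta: float
) -> AccuracyReport:
    e1 = original.edge_set()
    e2 = reconstructed.edge_set()
    nodes = list(dict.fromkeys(original.nodes + reconstructed.nodes))
    return AccuracyReport(
        jaccard_index=jaccard_index(e1, e2),
        rand_index=rand_index(e1, e2, nodes),
        theta=theta,
        n_original=len(e1),
        n_reconstructed=len(e2),
        n_intersection=len(e1 & e2),
        n_union=len(e1 | e2),
    )
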