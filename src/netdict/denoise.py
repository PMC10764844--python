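"""Edge/nonedge classification from reconstruction weights, with baselines.

The denoising task: given an observed (corrupted) graph G_obs, score
candidate node pairs by the confidence that each is a true edge of the
uncorrupted graph G_true.  For additive noise the candidates are all edges
of G_obs; for subtractive noise they are the deleted true edges plus an
equal number of never-existing nonedges sampled with probability
proportional to the product of endpoint degrees in G_obs (to defeat
trivially degree-based classification).  Throughout, label 1 means "true
edge of G_true" and higher scores mean more confidence that the pair is a
true edge, so AUC > 0.5 always means the method works.

Scorers: NDR reconstruction weights (learned from G_obs alone) and four
classical link-prediction baselines — Jaccard coefficient
|N(x) ∩ N(y)| / |N(x) ∪ N(y)|, preferential attachment |N(x)| * |N(y)|,
Adamic–Adar sum over common neighbors of 1 / ln|N(z)| (degree-1 common
neighbors skipped), and a rank-d adjacency spectral embedding with
dot-product scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph_core import Graph, GraphError, edge_key
from .generators import CorruptionRecord
from .ndl import NetworkDictionary, learn_dictionary, remove_on_chain
from .ndr import default_num_paths, reconstruct
from .sampling import PathSampler

__all__ = [
    "ScoredPairs",
    "candidate_sets",
    "baseline_scores",
    "ndr_scores",
    "four_dictionary_scores",
    "roc_auc",
    "select_threshold",
    "ThresholdReport",
]

BASELINE_METHODS = ("jaccard", "pref_attach", "adamic_adar", "spectral")


@dataclass
class ScoredPairs:
    """Candidate node pairs with confidence scores and ground-truth labels."""

    pairs: List[Tuple[str, str]]
    scores: np.ndarray
    labels: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (len(self.pairs) == len(self.scores) == len(self.labels)):
            raise GraphError("pairs, scores and labels must align")
        if not np.isfinite(self.scores).all():
            raise GraphError("scores must be finite")
        if not np.isin(self.labels, (0, 1)).all():
            raise GraphError("labels must be binary")


def candidate_sets(
    rec: CorruptionRecord, seed=None
) -> Tuple[List[Tuple[str, str]], np.ndarray]:
    """Candidate pairs and labels (1 = true edge of G_true) for a record.

    Additive noise: every edge of G_obs, labeled by membership in G_true.
    Subtractive noise: every removed edge (label 1) plus an equal number of
    nonedges of G_true (label 0), sampled without replacement with
    probability proportional to deg(u) * deg(v) in G_obs.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if rec.noise_type.startswith("+"):
        pairs = [edge_key(u, v) for u, v in rec.observed.edges()]
        truth = rec.truth.edge_set()
        labels = np.array([1 if p in truth else 0 for p in pairs])
        return pairs, labels
    # subtractive
    removed = sorted(rec.removed_edges)
    n_need = len(removed)
    g = rec.observed
    labels_list = g.nodes
    n = len(labels_list)
    truth_edges = rec.truth.edge_set()
    deg = np.array([g.degree(v) for v in labels_list], dtype=np.float64)
    if deg.sum() == 0:
        raise GraphError("observed graph has no edges to bias sampling")
    p_node = deg / deg.sum()
    chosen: set = set()
    max_tries = 1000 * max(1, n_need)
    tries = 0
    while len(chosen) < n_need:
        tries += 1
        if tries > max_tries:
            raise GraphError("could not sample enough biased nonedges")
        i = int(rng.choice(n, p=p_node))
        j = int(rng.choice(n, p=p_node))
        if i == j:
            continue
        key = edge_key(labels_list[i], labels_list[j])
        if key in truth_edges or key in chosen:
            continue
        chosen.add(key)
    pairs = removed + sorted(chosen)
    labels = np.array([1] * len(removed) + [0] * len(chosen))
    return pairs, labels


def _neighbor_sets(g: Graph) -> List[set]:
    adj = [set(s) for s in g._adj]
    for i, s in enumerate(adj):
        s.discard(i)  # self-edges do not count as neighbors here
    return adj


def baseline_scores(
    g_obs: Graph,
    pairs: Sequence[Tuple[str, str]],
    method: str,
    labels: Optional[np.ndarray] = None,
    spectral_dim: int = 32,
) -> ScoredPairs:
    """Classical link-prediction scores for candidate pairs on G_obs only."""
    if method not in BASELINE_METHODS:
        raise GraphError(f"unknown baseline {method!r}")
    if labels is None:
        labels = np.zeros(len(pairs), dtype=np.int64)
    if method == "spectral":
        scores = _spectral_scores(g_obs, pairs, spectral_dim)
        return ScoredPairs(list(pairs), scores, labels, method)
    adj = _neighbor_sets(g_obs)
    idx = {v: i for i, v in enumerate(g_obs.nodes)}
    scores = np.zeros(len(pairs))
    for t, (u, v) in enumerate(pairs):
        nu, nv = adj[idx[u]], adj[idx[v]]
        if method == "jaccard":
            union = len(nu | nv)
            scores[t] = len(nu & nv) / union if union else 0.0
        elif method == "pref_attach":
            scores[t] = len(nu) * len(nv)
        else:  # adamic_adar
            s = 0.0
            for z in nu & nv:
                dz = len(adj[z])
                if dz > 1:  # ln(1) = 0 would diverge; skip degree-1 terms
                    s += 1.0 / np.log(dz)
            scores[t] = s
    return ScoredPairs(list(pairs), scores, labels, method)


def _spectral_scores(
    g_obs: Graph, pairs: Sequence[Tuple[str, str]], d: int
) -> np.ndarray:
    """Rank-d adjacency spectral embedding; the score of a pair is the
    corresponding entry of the rank-d eigendecomposition of A."""
    from scipy.sparse.linalg import eigsh

    A = g_obs.adjacency_csr()
    n = A.shape[0]
    d_eff = min(d, n - 1)
    if d_eff < 1:
        raise GraphError("graph too small for a spectral embedding")
    vals, vecs = eigsh(A, k=d_eff, which="LM")
    idx = {v: i for i, v in enumerate(g_obs.nodes)}
    scores = np.zeros(len(pairs))
    for t, (u, v) in enumerate(pairs):
        iu, iv = idx[u], idx[v]
        scores[t] = float(np.sum(vals * vecs[iu] * vecs[iv]))
    return scores


def ndr_scores(
    rec: CorruptionRecord,
    pairs: Sequence[Tuple[str, str]],
    labels: Optional[np.ndarray] = None,
    nd: Optional[NetworkDictionary] = None,
    k: int = 21,
    r: int = 25,
    mask_on_chain: bool = False,
    T_learn: int = 50,
    N: int = 500,
    T_paths: Optional[int] = None,
    lam: float = 0.0,
    seed: Optional[int] = None,
) -> ScoredPairs:
    """Score candidate pairs by their NDR reconstruction weights.

    The dictionary is learned from the observed (corrupted) graph only; the
    score of a pair is its weight in G_recons (0 if never covered).
    """
    g = rec.observed
    sampler = PathSampler(g, nd.k if nd is not None else k)
    if nd is None:
        nd = learn_dictionary(
            g, k, r, T=T_learn, N=N, lam=lam, seed=seed, sampler=sampler
        )
    wg = reconstruct(
        g, nd, T=T_paths, lam=lam, mask_on_chain=mask_on_chain,
        seed=seed, sampler=sampler,
    )
    if labels is None:
        labels = np.zeros(len(pairs), dtype=np.int64)
    scores = np.array([wg.weight(u, v) for u, v in pairs])
    tag = f"ndr(k={nd.k},r={nd.r}{',masked' if mask_on_chain else ''})"
    return ScoredPairs(list(pairs), scores, labels, tag)


def four_dictionary_scores(
    rec: CorruptionRecord,
    pairs: Sequence[Tuple[str, str]],
    labels: Optional[np.ndarray] = None,
    k: int = 21,
    rs: Tuple[int, int] = (2, 25),
    seed: Optional[int] = None,
    **kwargs,
) -> Dict[str, ScoredPairs]:
    """The full protocol: r in {2, 25} x {W, W-bar} -> four score sets."""
    out: Dict[str, ScoredPairs] = {}
    for r in rs:
        g = rec.observed
        sampler = PathSampler(g, k)
        nd = learn_dictionary(
            g, k, r,
            T=kwargs.get("T_learn", 50), N=kwargs.get("N", 500),
            lam=kwargs.get("lam", 0.0), seed=seed, sampler=sampler,
        )
        for masked in (False, True):
            sp = ndr_scores(
                rec, pairs, labels, nd=nd, mask_on_chain=masked,
                T_paths=kwargs.get("T_paths"), lam=kwargs.get("lam", 0.0),
                seed=seed,
            )
            out[sp.method] = sp
    return out


def roc_auc(sp: ScoredPairs) -> Tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) from a full threshold sweep, and the AUC.

    The AUC equals the tie-corrected Mann–Whitney probability that a random
    positive outscores a random negative.
    """
    from sklearn.metrics import roc_curve, auc

    if sp.labels.min() == sp.labels.max():
        raise GraphError("ROC/AUC undefined: only one class present")
    fpr, tpr, _ = roc_curve(sp.labels, sp.scores)
    return np.column_stack([fpr, tpr]), float(auc(fpr, tpr))


@dataclass
class ThresholdReport:
    theta: float
    train_accuracy: float
    accuracy: float
    precision: float
    recall: float
    f_score: float


def select_threshold(
    sp: ScoredPairs, train_fraction: float = 0.5, seed=None
) -> ThresholdReport:
    """Pick the score threshold maximizing accuracy on a random training
    split; report held-out accuracy, precision, recall and F-score
    (harmonic mean of precision and recall)."""
    rng = np.random.default_rng(seed)
    n = len(sp.pairs)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    tr, te = order[:n_train], order[n_train:]
    if len(te) == 0 or len(tr) == 0:
        raise GraphError("degenerate train/test split")
    for part in (tr, te):
        if sp.labels[part].min() == sp.labels[part].max():
            raise GraphError("a split contains a single class")
    s_tr, y_tr = sp.scores[tr], sp.labels[tr]
    uniq = np.unique(s_tr)
    # candidate cuts: below the minimum, between consecutive scores
    cuts = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1]]])
    best_theta, best_acc = cuts[0], -1.0
    for c in cuts:
        acc = float(np.mean((s_tr > c).astype(int) == y_tr))
        if acc > best_acc:
            best_acc, best_theta = acc, float(c)
    s_te, y_te = sp.scores[te], sp.labels[te]
    pred = (s_te > best_theta).astype(int)
    tp = int(np.sum((pred == 1) & (y_te == 1)))
    fp = int(np.sum((pred == 1) & (y_te == 0)))
    fn = int(np.sum((pred == 0) & (y_te == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return ThresholdReport(
        theta=best_theta,
        train_accuracy=best_acc,
        accuracy=float(np.mean(pred == y_te)),
        precision=precision,
        recall=recall,
        f_score=f,
    )
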