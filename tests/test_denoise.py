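from collections import Counter

import numpy as np
import pytest

from netdict import (
    Graph,
    GraphError,
    ScoredPairs,
    baseline_scores,
    candidate_sets,
    chain_dictionary,
    corrupt_add_er,
    corrupt_subtract_er,
    er_graph,
    ndr_scores,
    path_graph,
    roc_auc,
    select_threshold,
)
from netdict.graph_core import edge_key

from conftest import complete_graph


def star_plus_clique():
    """Star (center s, 4 leaves) plus a disjoint 4-clique, joined by a bridge."""
    g = Graph()
    for i in range(1, 5):
        g.add_edge("s", f"l{i}")
    names = [f"q{i}" for i in range(4)]
    for i in range(4):
        for j in range(i + 1, 4):
            g.add_edge(names[i], names[j])
    g.add_edge("l1", "q0")  # keep it connected
    return g


class TestCandidateSets:
    def test_additive_candidates_are_observed_edges(self):
        g = path_graph(21)  # 20 edges
        rec = corrupt_add_er(g, "uniform", seed=0)
        pairs, labels = candidate_sets(rec, seed=1)
        assert len(pairs) == 30  # 20 true + 10 added
        assert labels.sum() == 20
        assert set(pairs) == rec.observed.edge_set()

    def test_subtractive_candidates_balanced(self):
        g = er_graph(30, 0.3, seed=2)
        assert g.is_connected()
        rec = corrupt_subtract_er(g, seed=3)
        pairs, labels = candidate_sets(rec, seed=4)
        n_removed = len(rec.removed_edges)
        assert len(pairs) == 2 * n_removed
        assert labels.sum() == n_removed
        # negatives are nonedges of the true graph
        truth = rec.truth.edge_set()
        for p, y in zip(pairs, labels):
            assert (p in truth) == bool(y)

    def test_degree_biased_nonedge_sampling(self):
        # high-degree-incident nonedges must be sampled more often, in
        # proportion to the product of endpoint degrees
        g = star_plus_clique()
        rec = corrupt_subtract_er(g, seed=0)
        if not rec.removed_edges:
            pytest.skip("no removable edge for this seed")
        counts = Counter()
        n_rounds = 400
        for s in range(n_rounds):
            pairs, labels = candidate_sets(rec, seed=s)
            for p, y in zip(pairs, labels):
                if y == 0:
                    counts[p] += 1
        # exhaustive weight oracle over eligible nonedges
        obs = rec.observed
        deg = {v: obs.degree(v) for v in obs.nodes}
        truth = rec.truth.edge_set()
        labels_all = obs.nodes
        weights = {}
        for i, u in enumerate(labels_all):
            for v in labels_all[i + 1:]:
                key = edge_key(u, v)
                if key not in truth:
                    weights[key] = deg[u] * deg[v]
        heavy = max(weights, key=weights.get)
        light = min(weights, key=weights.get)
        assert counts[heavy] > counts[light]


class TestBaselineScores:
    def test_star_formulas_exact(self):
        g = Graph(edges=[("c", "l1"), ("c", "l2"), ("c", "l3")])
        pairs = [("l1", "l2"), ("c", "l1")]
        pa = baseline_scores(g, pairs, "pref_attach").scores
        assert pa.tolist() == [1.0, 3.0]
        jc = baseline_scores(g, pairs, "jaccard").scores
        assert jc[0] == 1.0  # N(l1) = N(l2) = {c}
        assert jc[1] == 0.0  # disjoint neighborhoods
        aa = baseline_scores(g, pairs, "adamic_adar").scores
        assert aa[0] == pytest.approx(1 / np.log(3))

    def test_clique_formulas_exact(self):
        g = complete_graph(5)
        pairs = [("0", "1")]
        assert baseline_scores(g, pairs, "pref_attach").scores[0] == 16.0
        # N(0)\{1} and N(1)\{0} share 3 nodes; union has 5 elements
        assert baseline_scores(g, pairs, "jaccard").scores[0] == pytest.approx(3 / 5)
        assert baseline_scores(g, pairs, "adamic_adar").scores[0] == pytest.approx(
            3 / np.log(4)
        )

    def test_adamic_adar_skips_degree_one_common_neighbors(self):
        g = Graph(edges=[("a", "z"), ("b", "z")])  # z has degree 2
        g.add_edge("a", "w")
        g.add_edge("b", "w")
        # make w degree 2 as well, then drop to degree-1 via separate node
        g2 = Graph(edges=[("a", "m"), ("b", "m")])
        # m has degree 2 -> contributes; no degree-1 common neighbor case
        # crafted graph: common neighbor with degree 1 is impossible (it
        # needs edges to both endpoints), so check ln guard via degree-2
        aa = baseline_scores(g2, [("a", "b")], "adamic_adar").scores[0]
        assert aa == pytest.approx(1 / np.log(2))

    def test_spectral_recovers_dense_block(self):
        g = complete_graph(8)
        g.add_node("iso")
        sp = baseline_scores(g, [("0", "1"), ("0", "iso")], "spectral", spectral_dim=4)
        assert sp.scores[0] > sp.scores[1]

    def test_unknown_method(self):
        with pytest.raises(GraphError):
            baseline_scores(path_graph(3), [("0", "1")], "nope")


class TestRocAuc:
    def test_perfect_separation(self):
        sp = ScoredPairs([("a", "b")] * 3, [0.9, 0.8, 0.1], [1, 1, 0], "t")
        _, auc = roc_auc(sp)
        assert auc == 1.0

    def test_all_ties_give_half(self):
        sp = ScoredPairs([("a", "b")] * 4, [0.5] * 4, [1, 1, 0, 0], "t")
        _, auc = roc_auc(sp)
        assert auc == 0.5

    def test_rank_statistic_by_hand(self):
        # pos {0.8, 0.2}, neg {0.5}: one win, one loss -> 0.5
        sp = ScoredPairs([("a", "b")] * 3, [0.8, 0.2, 0.5], [1, 1, 0], "t")
        _, auc = roc_auc(sp)
        assert auc == 0.5

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1  # both classes present
        sp1 = ScoredPairs([("a", "b")] * 50, scores, labels, "t")
        sp2 = ScoredPairs([("a", "b")] * 50, np.exp(3 * scores), labels, "t")
        assert roc_auc(sp1)[1] == pytest.approx(roc_auc(sp2)[1])

    def test_single_class_undefined(self):
        sp = ScoredPairs([("a", "b")] * 2, [0.5, 0.6], [1, 1], "t")
        with pytest.raises(GraphError):
            roc_auc(sp)


class TestSelectThreshold:
    def test_perfect_separation_heldout_accuracy_one(self):
        n = 40
        scores = np.concatenate([np.linspace(0.6, 1, n // 2), np.linspace(0, 0.4, n // 2)])
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        sp = ScoredPairs([("a", "b")] * n, scores, labels, "t")
        rep = select_threshold(sp, seed=0)
        assert rep.accuracy == 1.0

    def test_uninformative_scores_near_chance(self):
        rng = np.random.default_rng(1)
        n = 400
        sp = ScoredPairs(
            [("a", "b")] * n, rng.random(n), rng.integers(0, 2, n), "t"
        )
        rep = select_threshold(sp, seed=2)
        assert abs(rep.accuracy - 0.5) < 0.15

    def test_all_positive_prediction_f_score(self):
        # equal scores force an all-positive or all-negative rule; with
        # prevalence 1/2 the all-positive rule wins and F = 2/3
        n = 40
        sp = ScoredPairs(
            [("a", "b")] * n,
            np.full(n, 0.5),
            np.array([1, 0] * (n // 2)),
            "t",
        )
        rep = select_threshold(sp, seed=3)
        assert rep.recall == 1.0
        assert rep.precision == pytest.approx(0.5, abs=0.15)
        assert rep.f_score == pytest.approx(2 / 3, abs=0.15)


class TestNdrScores:
    def test_k2_dictionary_cannot_discriminate(self):
        # at k = 2 every observed edge reconstructs to weight 1, so the AUC
        # on additive noise is exactly the chance level 0.5
        g = er_graph(40, 0.12, seed=6)
        rec = corrupt_add_er(g, "uniform", seed=7)
        pairs, labels = candidate_sets(rec, seed=8)
        m = rec.observed.number_of_edges()
        sp = ndr_scores(
            rec, pairs, labels, nd=chain_dictionary(2),
            T_paths=int(m * (np.log(m) + 6)), seed=9,
        )
        assert np.allclose(sp.scores, 1.0)
        _, auc = roc_auc(sp)
        assert auc == 0.5

    def test_scores_are_reconstruction_weights(self):
        g = path_graph(20)
        rec = corrupt_add_er(g, "uniform", seed=1)
        pairs, labels = candidate_sets(rec, seed=2)
        sp = ndr_scores(
            rec, pairs, labels, k=3, r=2, T_learn=5, N=50, T_paths=500, seed=3
        )
        assert sp.scores.min() >= 0.0 and sp.scores.max() <= 1.0
        assert len(sp.scores) == len(pairs)
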