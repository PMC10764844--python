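import warnings

import numpy as np
import pytest
from scipy.optimize import nnls

from netdict import (
    GraphError,
    NetworkDictionary,
    chain_dictionary,
    code_patches,
    learn_dictionary,
    motif_communities,
    path_graph,
    remove_on_chain,
    update_dictionary,
    vectorize,
)
from netdict.graph_core import on_chain_positions
from netdict.ndl import AggregateStats, surrogate_objective

from conftest import complete_graph, two_patch_type_graph


def offchain_mask(k):
    return (~on_chain_positions(k)) & ~np.eye(k, dtype=bool)


class TestCodePatches:
    def test_self_coding_is_exact(self):
        rng = np.random.default_rng(0)
        w = rng.random((25, 1))
        h = code_patches(w[:, 0], w)
        assert h.shape == (1, 1)
        assert abs(h[0, 0] - 1.0) < 1e-6
        assert np.linalg.norm(w @ h - w) < 1e-6

    def test_zero_vector_codes_to_zero(self):
        rng = np.random.default_rng(1)
        W = rng.random((16, 3))
        h = code_patches(np.zeros(16), W)
        assert np.allclose(h, 0.0)

    def test_chain_plus_offchain_closed_form(self):
        # single chain atom; patch = chain + one symmetric off-chain pair;
        # 1-D NNLS gives h = <x,w>/<w,w> = 1 and L1 residual 2
        k = 5
        chain = on_chain_positions(k).astype(float)
        w = vectorize(chain)
        x = w.copy()
        m = chain.copy()
        m[0, 2] = m[2, 0] = 1.0
        x = vectorize(m)
        h = code_patches(x, w[:, None])
        assert abs(h[0, 0] - 1.0) < 1e-6
        assert abs(np.abs(x - w * h[0, 0]).sum() - 2.0) < 1e-6
        # grid-search oracle over h in [0, 2]
        grid = np.arange(0, 2.0001, 1e-4)
        obj = ((x[:, None] - np.outer(w, grid)) ** 2).sum(axis=0)
        assert abs(grid[obj.argmin()] - h[0, 0]) < 1e-3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_nnls(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.random((30, 5))
        x = rng.random(30)
        h_ours = code_patches(x, W)[:, 0]
        h_ref, _ = nnls(W, x)
        assert np.allclose(h_ours, h_ref, atol=1e-5)

    def test_l1_penalty_shrinks_codes(self):
        rng = np.random.default_rng(3)
        W = rng.random((20, 4))
        x = rng.random(20)
        h0 = code_patches(x, W, lam=0.0).sum()
        h1 = code_patches(x, W, lam=1.0).sum()
        assert h1 < h0

    def test_dimension_mismatch(self):
        with pytest.raises(GraphError):
            code_patches(np.zeros(9), np.zeros((16, 2)))


class TestUpdateDictionary:
    def test_fixed_point_single_motif(self):
        rng = np.random.default_rng(0)
        w = rng.random((9, 1))
        stats = AggregateStats(P=np.array([[1.0]]), Q=w.copy(), t=1)
        assert np.allclose(update_dictionary(w, stats), w)

    def test_identity_P_moves_columns_to_Q(self):
        rng = np.random.default_rng(1)
        W = rng.random((9, 3))
        target = rng.random((9, 3)) * 1.5  # some entries will clip at 1
        stats = AggregateStats(P=np.eye(3), Q=target, t=1)
        out = update_dictionary(W, stats, n_passes=1)
        assert np.allclose(out, np.clip(target, 0, 1))

    def test_converges_under_stationary_aggregates(self):
        rng = np.random.default_rng(2)
        W = rng.random((16, 4))
        H = rng.random((4, 50))
        X = np.clip(rng.random((16, 4)) @ H + 0.05 * rng.random((16, 50)), 0, 1)
        stats = AggregateStats(P=H @ H.T / 50, Q=X @ H.T / 50, t=1)
        prev = W
        for _ in range(500):
            new = update_dictionary(prev, stats, n_passes=1)
            if np.abs(new - prev).max() < 1e-6:
                break
            prev = new
        assert np.abs(new - prev).max() < 1e-6

    def test_surrogate_never_increases(self):
        rng = np.random.default_rng(3)
        W = rng.random((16, 3))
        H = rng.random((3, 40))
        X = rng.random((16, 40))
        stats = AggregateStats(P=H @ H.T / 40, Q=X @ H.T / 40, t=1)
        obj = surrogate_objective(W, stats)
        for _ in range(10):
            W = update_dictionary(W, stats, n_passes=1)
            new_obj = surrogate_objective(W, stats)
            assert new_obj <= obj + 1e-10
            obj = new_obj

    def test_unused_motif_skipped_with_warning(self):
        rng = np.random.default_rng(4)
        W = rng.random((9, 2))
        P = np.array([[1.0, 0.0], [0.0, 0.0]])
        stats = AggregateStats(P=P, Q=np.zeros((9, 2)), t=1)
        with pytest.warns(RuntimeWarning, match="unused"):
            out = update_dictionary(W, stats, n_passes=1)
        assert np.allclose(out[:, 1], W[:, 1])

    def test_empty_stats_rejected(self):
        with pytest.raises(GraphError):
            update_dictionary(
                np.zeros((4, 1)),
                AggregateStats(P=np.zeros((1, 1)), Q=np.zeros((4, 1)), t=0),
            )


class TestLearnDictionary:
    def test_pure_path_recovers_chain_motif(self):
        g = path_graph(100)
        nd = learn_dictionary(g, k=5, r=1, T=20, N=200, seed=0)
        motif = nd.motif(0)
        assert motif[offchain_mask(5)].max() < 0.05

    def test_complete_graph_recovers_clique_motif(self):
        from netdict import mean_patch_l1_error

        g = complete_graph(30)
        nd = learn_dictionary(g, k=5, r=1, T=20, N=200, seed=0)
        motif = nd.motif(0)
        off_diag = ~np.eye(5, dtype=bool)
        assert motif[off_diag].min() > 0.9
        err = mean_patch_l1_error(g, nd, n_samples=100, seed=1)
        assert err.mean < 0.05

    def test_two_patch_types_need_two_motifs(self):
        from netdict import mean_patch_l1_error

        g = two_patch_type_graph()
        nd2 = learn_dictionary(g, k=3, r=2, T=60, N=300, seed=0)
        nd1 = learn_dictionary(g, k=3, r=1, T=60, N=300, seed=0)
        err2 = mean_patch_l1_error(g, nd2, n_samples=400, seed=1).mean
        err1 = mean_patch_l1_error(g, nd1, n_samples=400, seed=1).mean
        assert err2 < 0.1
        assert err1 > err2

    def test_entries_stay_in_unit_interval(self):
        g = two_patch_type_graph(40, 20)
        nd = learn_dictionary(g, k=4, r=3, T=10, N=100, seed=5)
        assert nd.W.min() >= 0.0 and nd.W.max() <= 1.0
        assert nd.W.any(axis=0).all()  # no all-zero motif

    def test_same_seed_is_bitwise_reproducible(self):
        g = path_graph(50)
        nd1 = learn_dictionary(g, k=4, r=2, T=5, N=50, seed=42)
        nd2 = learn_dictionary(g, k=4, r=2, T=5, N=50, seed=42)
        assert np.array_equal(nd1.W, nd2.W)

    def test_save_load_round_trip(self, tmp_path):
        g = path_graph(30)
        nd = learn_dictionary(g, k=3, r=2, T=3, N=30, seed=0)
        path = tmp_path / "dict.json"
        nd.save(path)
        loaded = NetworkDictionary.load(path)
        assert loaded.k == nd.k and loaded.r == nd.r
        assert np.array_equal(loaded.W, nd.W)


class TestRemoveOnChain:
    def test_chain_motif_becomes_zero(self):
        nd = chain_dictionary(6)
        assert not remove_on_chain(nd).W.any()

    def test_offchain_pair_survives(self):
        k = 5
        m = on_chain_positions(k).astype(float)
        m[0, 2] = m[2, 0] = 0.7
        nd = NetworkDictionary(k=k, r=1, W=vectorize(m)[:, None])
        out = remove_on_chain(nd).motif(0)
        assert out[0, 2] == 0.7 and out[2, 0] == 0.7
        assert out.sum() == pytest.approx(1.4)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        nd = NetworkDictionary(k=4, r=3, W=rng.random((16, 3)))
        once = remove_on_chain(nd)
        twice = remove_on_chain(once)
        assert np.array_equal(once.W, twice.W)


class TestMotifCommunities:
    def test_no_offchain_gives_singletons(self):
        sizes = motif_communities(on_chain_positions(6).astype(float), 0.5)
        assert sizes == [1] * 6

    def test_full_clique_single_component(self):
        k = 5
        m = np.ones((k, k)) - np.eye(k)
        assert motif_communities(m, 0.5) == [k]

    def test_two_offchain_edges_form_component(self):
        k = 5
        m = on_chain_positions(k).astype(float)
        m[0, 2] = m[2, 0] = 0.9
        m[2, 4] = m[4, 2] = 0.9
        sizes = motif_communities(m, 0.5)
        assert sizes == [3, 1, 1]
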