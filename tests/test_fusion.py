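import numpy as np
import pytest

import midti._autodiff as ad
from midti.data_io import SimilarityMatrix
from midti.fusion import (FusionConfig, encode_view, fuse_baseline,
                          fuse_networks, fusion_loss, reconstruct,
                          view_attention)
from midti.gcn import normalize_adjacency
from midti.simnet import ViewSet, jaccard_similarity


def _views(arrays, prefix="v"):
    return ViewSet([SimilarityMatrix(a, view_name=f"{prefix}{i}")
                    for i, a in enumerate(arrays)])


def _block_views(rng, n=20, n_views=3, p_noise=0.05):
    """Similarity views sharing a planted 2-block structure."""
    labels = np.arange(n) % 2
    out = []
    for _ in range(n_views):
        base = np.where(labels[:, None] == labels[None, :], 0.8, 0.1)
        noise = rng.normal(scale=p_noise, size=(n, n))
        s = np.clip(base + (noise + noise.T) / 2, 0, 1)
        np.fill_diagonal(s, 1.0)
        out.append(s)
    return _views(out), labels


class TestEncodeView:
    def test_identity_adjacency_gives_scaled_one_hot(self):
        w = ad.tensor(np.eye(4))
        out = encode_view(np.eye(4), w)
        np.testing.assert_allclose(out.data, np.tanh(np.eye(4)))

    def test_node_permutation_equivariance(self, rng):
        a = rng.random((6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        w = rng.normal(size=(6, 3))
        perm = rng.permutation(6)
        p = np.eye(6)[perm]
        out = encode_view(a, ad.tensor(w)).data
        out_perm = encode_view(p @ a @ p.T, ad.tensor(p @ w)).data
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-12)

    def test_path_graph_matches_dense_oracle(self, rng):
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        w = rng.normal(size=(3, 2))
        a_tilde = a + np.eye(3)
        d = np.diag(1 / np.sqrt(a_tilde.sum(1)))
        expected = np.tanh(d @ a_tilde @ d @ w)
        np.testing.assert_allclose(encode_view(a, ad.tensor(w)).data, expected)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            encode_view(np.zeros((3, 4)), ad.tensor(np.eye(4)))


class TestViewAttention:
    def test_identical_views_convexity(self, rng):
        emb = ad.tensor(rng.normal(size=(5, 4)))
        score = ad.tensor(rng.normal(size=(4, 1)))
        fused, weights = view_attention([emb, emb, emb], score)
        np.testing.assert_allclose(fused.data, emb.data, atol=1e-12)
        np.testing.assert_allclose(weights.data.sum(1), 1.0)

    def test_single_view(self, rng):
        emb = ad.tensor(rng.normal(size=(5, 4)))
        fused, weights = view_attention([emb], ad.tensor(rng.normal(size=(4, 1))))
        np.testing.assert_allclose(weights.data, 1.0)
        np.testing.assert_allclose(fused.data, emb.data)

    def test_forced_logits_softmax_oracle(self):
        """Logits (0, ln 3) per node must give weights (0.25, 0.75)."""
        score = ad.tensor(np.array([[1.0], [0.0]]))
        emb0 = ad.tensor(np.zeros((3, 2)))
        emb1 = ad.tensor(np.column_stack([np.full(3, np.log(3.0)),
                                          np.zeros(3)]))
        _, weights = view_attention([emb0, emb1], score)
        np.testing.assert_allclose(weights.data,
                                   np.tile([0.25, 0.75], (3, 1)), atol=1e-12)

    def test_va_off_is_unweighted_mean(self, rng):
        embs = [ad.tensor(rng.normal(size=(4, 3))) for _ in range(3)]
        fused, weights = view_attention(embs, ad.tensor(rng.normal(size=(3, 1))),
                                        va=False)
        np.testing.assert_allclose(weights.data, 1 / 3)
        np.testing.assert_allclose(fused.data,
                                   np.mean([e.data for e in embs], axis=0))

    def test_empty_views_rejected(self):
        with pytest.raises(ValueError):
            view_attention([], ad.tensor(np.zeros((2, 1))))


class TestReconstruct:
    def test_zero_features_give_half(self):
        out = reconstruct(ad.tensor(np.zeros((4, 3))))
        np.testing.assert_allclose(out.data, 0.5)

    def test_symmetry(self, rng):
        out = reconstruct(ad.tensor(rng.normal(size=(6, 3)))).data
        np.testing.assert_allclose(out, out.T)

    def test_scalar_logistic_oracle(self):
        out = reconstruct(ad.tensor(np.array([[1.0], [-1.0]])))
        assert out.data[0, 1] == pytest.approx(1 / (1 + np.e), rel=1e-12)


class TestFusionLoss:
    def test_zero_at_perfect_reconstruction(self, rng):
        a = rng.random((5, 5))
        loss = fusion_loss(ad.tensor(a), [a, a])
        assert float(loss.data) == pytest.approx(0.0, abs=1e-15)

    def test_epsilon_squared(self):
        a = np.full((4, 4), 0.3)
        loss = fusion_loss(ad.tensor(a + 0.05), [a])
        assert float(loss.data) == pytest.approx(0.05 ** 2)

    def test_view_order_invariance(self, rng):
        a_hat = ad.tensor(rng.random((5, 5)))
        views = [rng.random((5, 5)) for _ in range(3)]
        l1 = float(fusion_loss(a_hat, views).data)
        l2 = float(fusion_loss(a_hat, views[::-1]).data)
        assert l1 == pytest.approx(l2)

    def test_nonnegative(self, rng):
        loss = fusion_loss(ad.tensor(rng.random((5, 5))),
                           [rng.random((5, 5))])
        assert float(loss.data) >= 0


class TestFuseNetworks:
    CFG = dict(dim=8, epochs=120, lr=0.01, seed=7)

    def test_duplicate_view_symmetry(self, rng):
        views, _ = _block_views(rng, n=12, n_views=1)
        single = fuse_networks(views, FusionConfig(**self.CFG))
        dup = ViewSet([SimilarityMatrix(views.views[0].values, view_name="a"),
                       SimilarityMatrix(views.views[0].values, view_name="b")])
        double = fuse_networks(dup, FusionConfig(**self.CFG))
        np.testing.assert_allclose(double.view_weights, 0.5, atol=1e-8)
        np.testing.assert_allclose(double.x, single.x, atol=1e-6)
        np.testing.assert_allclose(double.a_homo.values, single.a_homo.values,
                                   atol=1e-6)

    def test_training_loss_decreases_in_running_mean(self, rng):
        views, _ = _block_views(rng)
        fused = fuse_networks(views, FusionConfig(dim=8, epochs=50, lr=0.01,
                                                  seed=0))
        h = np.asarray(fused.loss_history)
        running = np.convolve(h, np.ones(10) / 10, mode="valid")
        assert running[-1] < running[0]
        assert np.all(np.diff(running) < 1e-3)  # non-increasing up to jitter

    def test_planted_blocks_recovered(self, rng):
        views, labels = _block_views(rng)
        fused = fuse_networks(views, FusionConfig(dim=8, epochs=300, lr=0.01,
                                                  seed=1))
        a = fused.a_homo.values
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(labels), dtype=bool)
        assert a[same & off_diag].mean() > a[~same].mean()

    def test_a_homo_satisfies_similarity_contract(self, rng):
        views, _ = _block_views(rng, n=10)
        fused = fuse_networks(views, FusionConfig(dim=4, epochs=30, lr=0.01,
                                                  seed=2))
        a = fused.a_homo.values
        np.testing.assert_allclose(a, a.T, atol=1e-8)
        assert a.min() >= 0 and a.max() <= 1
        np.testing.assert_allclose(np.diag(a), 1.0)
        np.testing.assert_allclose(fused.view_weights.sum(1), 1.0, atol=1e-6)


class TestFuseBaseline:
    def test_ave_of_identical_views_unchanged(self, rng):
        views, _ = _block_views(rng, n=8, n_views=1)
        a = views.views[0].values
        dup = _views([a, a.copy()])
        np.testing.assert_allclose(fuse_baseline(dup, "ave").values, a)

    def test_ave_entrywise_mean(self):
        a = np.full((3, 3), 0.2)
        b = np.full((3, 3), 0.4)
        for m in (a, b):
            np.fill_diagonal(m, 1.0)
        out = fuse_baseline(_views([a, b]), "ave").values
        assert out[0, 1] == pytest.approx(0.3)

    def test_pro_noisy_or(self):
        a = np.full((3, 3), 0.2)
        b = np.full((3, 3), 0.4)
        for m in (a, b):
            np.fill_diagonal(m, 1.0)
        out = fuse_baseline(_views([a, b]), "pro").values
        assert out[0, 1] == pytest.approx(1 - 0.8 * 0.6)
        assert out[0, 0] == 1.0

    def test_literal_pro_escape_hatch(self):
        a = np.full((3, 3), 0.2)
        b = np.full((3, 3), 0.4)
        for m in (a, b):
            np.fill_diagonal(m, 1.0)
        out = fuse_baseline(_views([a, b]), "pro", literal_pro=True).values
        assert out[0, 1] == pytest.approx(1 - 0.2 * 0.4)

    def test_unknown_strategy_rejected(self, rng):
        views, _ = _block_views(rng, n=6, n_views=1)
        with pytest.raises(ValueError):
            fuse_baseline(views, "median")
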