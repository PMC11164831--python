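import numpy as np
import pytest

import midti._autodiff as ad
from midti.attention import (AttentionBlock, AttentionConfig, FeedForward,
                             InteractiveAttention, InteractiveLayer,
                             LayerNorm, MultiHeadAttention, dta_block, pool,
                             record_attention, sa_block, scaled_dot_attention,
                             tda_block)


class TestScaledDotAttention:
    def test_single_key_returns_value_row(self, rng):
        q = ad.tensor(rng.normal(size=(3, 4)))
        k = ad.tensor(rng.normal(size=(1, 4)))
        v = ad.tensor(rng.normal(size=(1, 5)))
        out = scaled_dot_attention(q, k, v)
        np.testing.assert_allclose(out.data, np.tile(v.data, (3, 1)))

    def test_rows_are_stochastic(self, rng):
        q = ad.tensor(rng.normal(size=(6, 4)))
        k = ad.tensor(rng.normal(size=(5, 4)))
        v = ad.tensor(rng.normal(size=(5, 4)))
        with record_attention() as probe:
            scaled_dot_attention(q, k, v)
        att = probe[0]
        assert att.min() >= 0
        np.testing.assert_allclose(att.sum(-1), 1.0, atol=1e-6)

    def test_two_by_two_softmax_oracle(self):
        """Q=K=I, d=1 → row 0 weights (e/(e+1), 1/(e+1))."""
        q = k = ad.tensor(np.eye(2))
        v = ad.tensor(np.eye(2))
        out = scaled_dot_attention(q, k, v, d=1.0)
        e = np.e
        np.testing.assert_allclose(out.data[0], [e / (e + 1), 1 / (e + 1)],
                                   atol=1e-12)

    def test_outputs_inside_value_hull(self, rng):
        q = ad.tensor(rng.normal(size=(4, 3)))
        k = ad.tensor(rng.normal(size=(5, 3)))
        v = ad.tensor(rng.normal(size=(5, 2)))
        out = scaled_dot_attention(q, k, v).data
        assert out.min() >= v.data.min() - 1e-12
        assert out.max() <= v.data.max() + 1e-12

    def test_dominant_key_pulls_output_to_its_value(self):
        """A key strongly aligned with the query dominates the convex
        combination, dragging the output onto that value row (the
        cross-attention guidance mechanism)."""
        q = ad.tensor(np.array([[10.0, 0.0]]))
        k = ad.tensor(np.array([[10.0, 0.0], [0.0, 10.0], [-10.0, 0.0]]))
        v = ad.tensor(np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]))
        out = scaled_dot_attention(q, k, v).data
        np.testing.assert_allclose(out[0], [1.0, 2.0], atol=1e-6)


class TestMultiHead:
    def test_matches_per_head_loop(self, rng):
        """Vectorised MHA equals an explicit per-head loop, tol 1e-5."""
        f_m, heads, s = 512, 8, 9
        mha = MultiHeadAttention(f_m, heads, np.random.default_rng(0))
        x = rng.normal(size=(s, f_m))
        out = mha(ad.tensor(x), ad.tensor(x)).data

        d = f_m // heads
        q = x @ mha.q.w.data
        k = x @ mha.k.w.data
        v = x @ mha.v.w.data
        head_outs = []
        for h in range(heads):
            sl = slice(h * d, (h + 1) * d)
            scores = q[:, sl] @ k[:, sl].T / np.sqrt(d)
            e = np.exp(scores - scores.max(1, keepdims=True))
            att = e / e.sum(1, keepdims=True)
            head_outs.append(att @ v[:, sl])
        expected = np.hstack(head_outs) @ mha.o.w.data
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_single_head_is_projected_scaled_dot(self, rng):
        f_m = 8
        mha = MultiHeadAttention(f_m, 1, np.random.default_rng(1))
        x = ad.tensor(rng.normal(size=(5, f_m)))
        out = mha(x, x).data
        q, k, v = (x.data @ mha.q.w.data, x.data @ mha.k.w.data,
                   x.data @ mha.v.w.data)
        inner = scaled_dot_attention(ad.tensor(q), ad.tensor(k),
                                     ad.tensor(v)).data
        np.testing.assert_allclose(out, inner @ mha.o.w.data, atol=1e-12)

    def test_head_width(self):
        mha = MultiHeadAttention(512, 8, np.random.default_rng(0))
        assert mha.d_head == 64

    def test_indivisible_width_rejected(self):
        with pytest.raises(ValueError):
            MultiHeadAttention(512, 7, np.random.default_rng(0))


class TestLayerNorm:
    def test_matches_hand_rolled_moments(self, rng):
        ln = LayerNorm(6)
        x = rng.normal(size=(4, 6), scale=3.0)
        out = ln(ad.tensor(x)).data
        mu = x.mean(-1, keepdims=True)
        sd = np.sqrt(x.var(-1, keepdims=True) + 1e-5)
        np.testing.assert_allclose(out, (x - mu) / sd, atol=1e-10)
        np.testing.assert_allclose(out.mean(-1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(-1), 1.0, atol=1e-2)


class TestBlocks:
    def _block(self, wrap="literal", dropout=0.0, seed=0):
        return AttentionBlock(8, 2, dropout, np.random.default_rng(seed),
                              wrap=wrap)

    def test_sa_eval_mode_deterministic(self, rng):
        block = self._block(dropout=0.5)
        x = ad.tensor(rng.normal(size=(2, 6, 8)))
        a = sa_block(block, x, training=False).data
        b = sa_block(block, x, training=False).data
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("rows", [3, 6, 9])
    def test_shape_preserved(self, rng, rows):
        block = self._block()
        x = ad.tensor(rng.normal(size=(2, rows, 8)))
        assert sa_block(block, x).shape == (2, rows, 8)

    def test_cross_block_shapes(self, rng):
        block = self._block()
        x_d = ad.tensor(rng.normal(size=(2, 6, 8)))
        x_t = ad.tensor(rng.normal(size=(2, 6, 8)))
        assert dta_block(block, x_d, x_t).shape == (2, 6, 8)

    def test_dta_tda_argument_symmetry(self, rng):
        """TDA is DTA with the roles swapped: one block applied to the
        swapped pair computes the same thing."""
        block = self._block()
        x_d = ad.tensor(rng.normal(size=(2, 6, 8)))
        x_t = ad.tensor(rng.normal(size=(2, 6, 8)))
        np.testing.assert_array_equal(dta_block(block, x_t, x_d).data,
                                      tda_block(block, x_t, x_d).data)

    def test_standard_wrap_runs(self, rng):
        block = self._block(wrap="standard")
        x = ad.tensor(rng.normal(size=(1, 4, 8)))
        assert sa_block(block, x).shape == (1, 4, 8)


class TestInteractiveLayer:
    def test_two_sa_calls_per_layer(self, rng):
        layer = InteractiveLayer(8, 2, 0.0, np.random.default_rng(0))
        x_d = ad.tensor(rng.normal(size=(2, 6, 8)))
        x_t = ad.tensor(rng.normal(size=(2, 6, 8)))
        layer(x_d, x_t)
        assert layer.sa_d.calls + layer.sa_t.calls == 2
        assert layer.dta.calls == 1 and layer.tda.calls == 1

    def test_matches_manual_composition(self, rng):
        layer = InteractiveLayer(8, 2, 0.0, np.random.default_rng(0))
        x_d = ad.tensor(rng.normal(size=(2, 6, 8)))
        x_t = ad.tensor(rng.normal(size=(2, 6, 8)))
        out_d, out_t = layer(x_d, x_t)
        s_d = sa_block(layer.sa_d, x_d)
        s_t = sa_block(layer.sa_t, x_t)
        np.testing.assert_array_equal(out_d.data,
                                      dta_block(layer.dta, s_d, s_t).data)
        np.testing.assert_array_equal(out_t.data,
                                      tda_block(layer.tda, s_t, s_d).data)


class TestCascade:
    def test_zero_layers_is_projection_of_input(self, rng):
        cfg = AttentionConfig(heads=2, n_layers=0, f_m=8, dropout=0.0, seed=0)
        ia = InteractiveAttention(cfg)
        x_d = ad.tensor(rng.normal(size=(2, 6, 8)))
        x_t = ad.tensor(rng.normal(size=(2, 6, 8)))
        out_d, out_t = ia(x_d, x_t)
        np.testing.assert_allclose(out_d.data, x_d.data @ ia.w_r.data)
        np.testing.assert_allclose(out_t.data, x_t.data @ ia.w_s.data)

    def test_default_depth_concatenates_four_terms(self):
        cfg = AttentionConfig()  # published defaults: 3 layers, F_m 512
        ia = InteractiveAttention(cfg)
        assert ia.w_r.shape == (4 * 512, 512)
        assert ia.w_s.shape == (4 * 512, 512)

    def test_deterministic_in_eval_mode(self, rng):
        cfg = AttentionConfig(heads=2, n_layers=2, f_m=8, dropout=0.3, seed=5)
        ia = InteractiveAttention(cfg)
        x_d = ad.tensor(rng.normal(size=(2, 6, 8)))
        x_t = ad.tensor(rng.normal(size=(2, 6, 8)))
        a = ia(x_d, x_t, training=False)[0].data
        b = ia(x_d, x_t, training=False)[0].data
        np.testing.assert_array_equal(a, b)

    def test_every_attention_matrix_row_stochastic(self, rng):
        cfg = AttentionConfig(heads=2, n_layers=2, f_m=8, dropout=0.0, seed=0)
        ia = InteractiveAttention(cfg)
        x_d = ad.tensor(rng.normal(size=(3, 6, 8)))
        x_t = ad.tensor(rng.normal(size=(3, 6, 8)))
        with record_attention() as probe:
            ia(x_d, x_t)
        assert len(probe) == 2 * 4  # 4 attention blocks per layer, 2 layers
        for att in probe:
            assert att.min() >= 0
            np.testing.assert_allclose(att.sum(-1), 1.0, atol=1e-6)


class TestPool:
    def test_identical_rows_give_that_row(self, rng):
        row = rng.normal(size=8)
        x = np.tile(row, (2, 5, 1))
        np.testing.assert_allclose(pool(ad.tensor(x)).data,
                                   np.tile(row, (2, 1)))

    def test_matches_column_mean_oracle(self, rng):
        x = rng.normal(size=(3, 6, 8))
        np.testing.assert_allclose(pool(ad.tensor(x)).data, x.mean(axis=1))

    def test_two_dim_input_pools_to_single_row(self, rng):
        x = rng.normal(size=(6, 8))
        out = pool(ad.tensor(x))
        assert out.shape == (1, 8)
        np.testing.assert_allclose(out.data[0], x.mean(axis=0))


class TestConfigValidation:
    def test_defaults_follow_published_operating_point(self):
        cfg = AttentionConfig()
        assert (cfg.f_m, cfg.heads, cfg.n_layers, cfg.dropout) == \
            (512, 8, 3, 0.1)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            AttentionConfig(heads=7, f_m=512)

    def test_negative_layers_rejected(self):
        with pytest.raises(ValueError):
            AttentionConfig(n_layers=-1)
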