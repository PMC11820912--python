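"""Closed-form checks, algebraic identities and gradient correctness of the
encoder architecture."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from wearaffect.network import (
    AdamOptimizer,
    FeatureExtractor,
    ModelConfig,
    TransformerClassifier,
    classify,
    cross_entropy,
    fuse_concat,
    positional_encoding,
    scaled_dot_attention,
    softmax,
)


class TestPositionalEncoding:
    def test_row_zero_alternates_zero_one(self):
        P = positional_encoding(5, 8)
        assert np.allclose(P[0, 0::2], 0.0)
        assert np.allclose(P[0, 1::2], 1.0)

    def test_first_step_first_dimension_is_sin_one(self):
        # P(1, 0) = sin(1/10000^0) = sin(1), independent of d
        for d in (4, 8, 64):
            assert positional_encoding(2, d)[1, 0] == pytest.approx(0.841471, abs=1e-6)

    def test_bounded_by_unit_interval(self):
        P = positional_encoding(50, 16)
        assert np.all(P >= -1.0) and np.all(P <= 1.0)

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(4, 7)


class TestAttention:
    def test_zero_query_averages_values(self, rng):
        K = rng.normal(size=(6, 4))
        V = rng.normal(size=(6, 4))
        out, A = scaled_dot_attention(np.zeros((3, 4)), K, V)
        assert np.allclose(out, V.mean(axis=0))
        assert np.allclose(A, 1.0 / 6)

    @given(H=arrays(np.float64, (4, 6), elements=st.floats(-50, 50)))
    def test_weight_rows_sum_to_one(self, H):
        _, A = scaled_dot_attention(H, H, H)
        assert np.allclose(A.sum(axis=-1), 1.0)

    def test_saturated_identity_attention(self):
        # Q = K = c·I with large c: each row attends to its own value row
        c = 50.0
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        out, _ = scaled_dot_attention(c * np.eye(2), c * np.eye(2), V)
        assert np.allclose(out, V, atol=1e-10)


def test_fuse_concat_order_and_inverse(rng):
    E = [rng.normal(size=(4, 2)) for _ in range(3)]
    fused = fuse_concat(*E)
    assert fused.shape == (4, 6)
    for m in range(3):
        assert np.array_equal(fused[:, 2 * m : 2 * m + 2], E[m])
    with pytest.raises(ValueError, match="T'"):
        fuse_concat(E[0], rng.normal(size=(5, 2)))


class TestClassify:
    def test_even_logits_split_evenly(self):
        p = classify(np.zeros(2), np.eye(2), np.zeros(2))
        assert np.allclose(p, [0.5, 0.5])

    def test_shift_invariance(self, rng):
        # adding a constant to all logits leaves probabilities unchanged
        E = rng.normal(size=4)
        W, b = rng.normal(size=(4, 3)), rng.normal(size=3)
        assert np.allclose(classify(E, W, b), classify(E, W, b + 123.4))

    def test_dominant_logit(self):
        p = softmax(np.array([10.0, 0, 0, 0, 0]))
        assert np.argmax(p) == 0 and p[0] > 0.99


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        assert cross_entropy([0.0, 1.0, 0.0], [0, 1, 0]) == 0.0

    def test_uniform_five_class(self):
        assert cross_entropy(np.full(5, 0.2), [1, 0, 0, 0, 0]) == pytest.approx(np.log(5))

    def test_frozen_binary_value(self):
        assert cross_entropy([0.7, 0.3], [1, 0]) == pytest.approx(0.35667, abs=1e-5)

    def test_zero_probability_clamped_finite(self):
        assert np.isfinite(cross_entropy([0.0, 1.0], [1, 0]))


class TestFeatureExtractor:
    def _cfg(self):
        return ModelConfig(embed_dim=3, cnn_hidden=4, d_model=8, n_heads=2, ffn_dim=8, dropout=0.0)

    def test_zero_input_zero_embedding(self, rng):
        fx = FeatureExtractor(self._cfg(), rng)  # biases initialise to zero
        emb = fx.forward(np.zeros((2, 16, 1)))
        assert np.allclose(emb, 0.0)

    def test_output_shape_and_purity(self, rng):
        fx = FeatureExtractor(self._cfg(), rng)
        x = rng.normal(size=(2, 16, 1))
        emb = fx.forward(x)
        assert emb.shape == (2, fx.out_length(16), 3)
        assert np.array_equal(emb, fx.forward(x))

    def test_too_short_input_rejected(self, rng):
        fx = FeatureExtractor(self._cfg(), rng)
        with pytest.raises(ValueError, match="receptive field"):
            fx.forward(np.zeros((1, 1, 1)))


def _identity_mha(mha):
    for lin in (mha.Wq, mha.Wk, mha.Wv, mha.Wo):
        lin.W.data[...] = np.eye(lin.W.data.shape[0])
        lin.b.data[...] = 0.0


class TestMultiHeadAttention:
    def test_single_head_identity_projections_reduce_to_plain_attention(self, rng):
        from wearaffect.network import MultiHeadSelfAttention

        mha = MultiHeadSelfAttention(6, 1, rng)
        _identity_mha(mha)
        H = rng.normal(size=(1, 5, 6))
        expected, _ = scaled_dot_attention(H[0], H[0], H[0])
        assert np.allclose(mha.forward(H)[0], expected)

    def test_output_shape_preserved_and_zero_projection(self, rng):
        from wearaffect.network import MultiHeadSelfAttention

        mha = MultiHeadSelfAttention(8, 2, rng)
        H = rng.normal(size=(2, 5, 8))
        assert mha.forward(H).shape == H.shape
        mha.Wo.W.data[...] = 0.0
        mha.Wo.b.data[...] = 0.0
        assert np.allclose(mha.forward(H), 0.0)

    def test_indivisible_width_rejected(self, rng):
        from wearaffect.network import MultiHeadSelfAttention

        with pytest.raises(ValueError):
            MultiHeadSelfAttention(6, 4, rng)


class TestEncoderLayer:
    def _layer(self, rng, layer_norm=False):
        from wearaffect.network import EncoderLayer

        cfg = ModelConfig(
            embed_dim=3, cnn_hidden=4, d_model=6, n_heads=2, ffn_dim=8, dropout=0.0,
            layer_norm=layer_norm,
        )
        return EncoderLayer(cfg, rng, np.random.default_rng(0))

    def test_zero_branch_is_identity(self, rng):
        """With the feed-forward branch zeroed and normalisation off, the
        residual makes the layer the identity map."""
        layer = self._layer(rng)
        layer.ffn.lin2.W.data[...] = 0.0
        layer.ffn.lin2.b.data[...] = 0.0
        H = rng.normal(size=(2, 5, 6))
        assert np.allclose(layer.forward(H, train=False), H)

    def test_stacking_preserves_shape(self, rng):
        H = np.random.default_rng(3).normal(size=(2, 5, 6))
        for _ in range(3):
            H_next = self._layer(rng, layer_norm=True).forward(H, train=False)
            assert H_next.shape == H.shape
            H = H_next

    def test_single_token_composition_matches_hand_trace(self, rng):
        # T'=1: attention weight is exactly 1, so the layer computes
        # FFN(Wo(Wv·h + bv) + bo) + h
        layer = self._layer(rng)
        H = rng.normal(size=(1, 1, 6))
        v = layer.mha.Wv.forward(H)
        attn_out = layer.mha.Wo.forward(v)
        expected = layer.ffn.forward(attn_out) + H
        assert np.allclose(layer.forward(H, train=False), expected)


class TestForward:
    def test_deterministic_probability_output(self, tiny_model_config, rng):
        m = TransformerClassifier(tiny_model_config, seed=7)
        X = rng.normal(size=(4, 16, 3))
        p1, p2 = m.predict_proba(X), m.predict_proba(X)
        assert np.array_equal(p1, p2)
        assert np.all(p1 >= 0) and np.allclose(p1.sum(axis=1), 1.0)

    def test_wrong_channel_count_rejected(self, tiny_model_config):
        m = TransformerClassifier(tiny_model_config, seed=0)
        with pytest.raises(ValueError, match="expected"):
            m.forward(np.zeros((1, 16, 2)))

    def test_dropout_only_active_in_training(self, rng):
        cfg = ModelConfig(embed_dim=3, cnn_hidden=4, d_model=8, n_heads=2, ffn_dim=8,
                          dropout=0.5, n_classes=2)
        m = TransformerClassifier(cfg, seed=0)
        X = rng.normal(size=(2, 16, 3))
        assert np.array_equal(m.forward(X, train=False), m.forward(X, train=False))
        assert not np.array_equal(m.forward(X, train=True), m.forward(X, train=True))


def _gradcheck(model, X, y, rng, per_param=4, eps=1e-6):
    # move off ReLU kinks: zero-initialised biases leave pre-activations
    # exactly at 0, where the subgradient and the one-sided finite
    # difference legitimately disagree
    for p in model.parameters():
        p.data += rng.normal(0.0, 0.01, size=p.data.shape)
    model.zero_grad()
    model.loss_and_grad(X, y, train=False)
    grads = [p.grad.copy() for p in model.parameters()]
    worst = 0.0
    for p, g in zip(model.parameters(), grads):
        flat, gf = p.data.ravel(), g.ravel()
        for i in rng.choice(flat.size, size=min(per_param, flat.size), replace=False):
            old = flat[i]
            flat[i] = old + eps
            model.zero_grad()
            l1 = model.loss_and_grad(X, y, train=False)
            flat[i] = old - eps
            model.zero_grad()
            l2 = model.loss_and_grad(X, y, train=False)
            flat[i] = old
            num = (l1 - l2) / (2 * eps)
            # floor the denominator at 1e-6: below that the central
            # difference itself carries ~1e-10 absolute error
            worst = max(worst, abs(num - gf[i]) / max(abs(num), abs(gf[i]), 1e-6))
    return worst


class TestGradients:
    def test_classifier_head_gradient_matches_finite_difference(self, tiny_model_config, rng):
        m = TransformerClassifier(tiny_model_config, seed=1)
        X = rng.normal(size=(3, 16, 3))
        y = np.array([0, 1, 0])
        m.zero_grad()
        m.loss_and_grad(X, y, train=False)
        g = m.head.W.grad.copy()
        eps = 1e-6
        flat = m.head.W.data.ravel()
        for i in range(0, flat.size, 5):
            old = flat[i]
            flat[i] = old + eps
            l1 = m.loss_and_grad(X, y, train=False)
            flat[i] = old - eps
            l2 = m.loss_and_grad(X, y, train=False)
            flat[i] = old
            num = (l1 - l2) / (2 * eps)
            assert abs(num - g.ravel()[i]) / max(abs(num), 1e-8) < 1e-4

    def test_all_parameters_gradcheck_small_model(self, tiny_model_config, rng):
        m = TransformerClassifier(tiny_model_config, seed=1)
        X = rng.normal(size=(3, 16, 3))
        y = np.array([0, 1, 0])
        assert _gradcheck(m, X, y, rng) < 1e-4

    def test_layernorm_and_cls_pooling_gradcheck(self, rng):
        cfg = ModelConfig(
            embed_dim=2, cnn_hidden=3, d_model=8, n_layers=1, n_heads=2, ffn_dim=8,
            dropout=0.0, n_classes=3, pooling="cls", layer_norm=True,
        )
        m = TransformerClassifier(cfg, seed=2)
        X = rng.normal(size=(2, 16, 3))
        y = np.array([2, 0])
        assert _gradcheck(m, X, y, rng, per_param=3) < 1e-4


def test_training_drives_separable_toy_to_perfect_accuracy(rng):
    """Mean-shifted channels (+/-2) are linearly separable; a small model
    must reach training accuracy 1.0 within 50 epochs."""
    cfg = ModelConfig(embed_dim=4, cnn_hidden=4, d_model=8, n_layers=1, n_heads=2,
                      ffn_dim=16, dropout=0.0, n_classes=2)
    n = 40
    y = np.arange(n) % 2
    X = rng.normal(size=(n, 16, 3)) + (2.0 * (2 * y - 1))[:, None, None]
    m = TransformerClassifier(cfg, seed=0)
    opt = AdamOptimizer(m.parameters(), lr=1e-3)
    for _ in range(50):
        m.zero_grad()
        m.loss_and_grad(X, y, train=True)
        opt.step()
        if np.mean(m.predict(X) == y) == 1.0:
            break
    assert np.mean(m.predict(X) == y) == 1.0
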