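"""Encoder building blocks: embeddings, sparse attention, loss, auROC."""

import math

import numpy as np
import pytest

import probatac.autodiff as ad
import probatac.model as M
from probatac.model import (ModelConfig, bce_loss, dense_attention_oracle,
                            mean_auroc, position_embedding, predict_accessibility,
                            sparse_attention, sparsity_measurement,
                            uniform_input)

RNG = np.random.default_rng(7)


def tiny_config(**kw):
    base = dict(input_length=20, n_cells=3, d=8, n_heads=2, n_layers=2,
                ffw_width=12, stem_kernel=5, enc_kernel=3, seq_channels=2,
                seq_kernel=3, embedding_size=4, stem_threshold=100,
                attention_mode="exact", seed=0)
    base.update(kw)
    return ModelConfig(**base)


# ---------------------------------------------------------------------------
# position / input embeddings
# ---------------------------------------------------------------------------


def test_position_embedding_closed_forms():
    pe = position_embedding(10, 6)
    assert np.allclose(pe[0, 0::2], 0.0)         # sin(0)
    assert np.allclose(pe[0, 1::2], 1.0)         # cos(0)
    assert np.allclose(pe[:, 0], np.sin(np.arange(10)))   # exponent 0
    assert np.all(np.abs(pe) <= 1.0)
    with pytest.raises(ValueError):
        position_embedding(4, 5)


def test_uniform_input_modes():
    u = RNG.random((2, 5, 4))
    pe = position_embedding(5, 4)
    assert np.allclose(uniform_input(u, pe, alpha=0.0), pe)
    assert np.allclose(uniform_input(u, None, alpha=2.0), 2 * u)   # WoPE
    assert np.allclose(uniform_input(np.zeros_like(u), pe, 1.0), pe)
    with pytest.raises(ValueError):
        uniform_input(u, position_embedding(6, 4), 1.0)


# ---------------------------------------------------------------------------
# sparsity measurement
# ---------------------------------------------------------------------------


def test_exact_measurement_constant_scores_is_log_lk():
    # identical q rows vs identical k rows -> all pair scores equal
    q = np.ones((6, 3))
    k = np.ones((9, 3))
    m = sparsity_measurement(q, k, mode="exact")
    assert np.allclose(m, math.log(9), atol=1e-12)


def test_sampled_measurement_constant_scores_is_zero():
    q = np.ones((6, 3))
    k = np.ones((9, 3))
    m = sparsity_measurement(q, k, mode="sampled", seed=4)
    assert np.allclose(m, 0.0, atol=1e-12)


def test_exact_measurement_two_point_closed_form():
    # d_h = 1, scores {2, 0}: M = ln(e^2 + 1) - 1
    q = np.array([[1.0]])
    k = np.array([[2.0], [0.0]])
    m = sparsity_measurement(q, k, mode="exact")
    assert np.allclose(m, math.log(math.exp(2) + 1) - 1.0, atol=1e-9)


def test_measurement_spike_increases_exact_score():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        q = rng.normal(size=(5, 4))
        k = rng.normal(size=(8, 4))
        base = sparsity_measurement(q, k, mode="exact")
        q_spiked = q.copy()
        q_spiked[2] = 10.0 * k[3] / np.linalg.norm(k[3])
        spiked = sparsity_measurement(q_spiked, k, mode="exact")
        assert spiked[2] > base[2]


def test_measurement_empty_keys_errors():
    with pytest.raises(ValueError):
        sparsity_measurement(np.ones((2, 3)), np.ones((0, 3)))


# ---------------------------------------------------------------------------
# sparse attention vs the dense oracle
# ---------------------------------------------------------------------------


def test_sparse_attention_equals_dense_oracle_when_all_queries_selected():
    for i in range(20):
        rng = np.random.default_rng(i)
        L = int(rng.integers(2, 64))
        d_h = int(rng.integers(1, 16))
        Q, K, V = (rng.normal(size=(L, d_h)) for _ in range(3))
        out = sparse_attention(Q, K, V, c=float(L), mode="exact")
        assert np.max(np.abs(out - dense_attention_oracle(Q, K, V))) < 1e-5


def test_non_selected_queries_get_mean_of_values():
    rng = np.random.default_rng(0)
    Q = np.zeros((10, 4))
    Q[0] = rng.normal(size=4) * 5          # only one query can dominate
    K, V = rng.normal(size=(7, 4)), rng.normal(size=(7, 4))
    out = sparse_attention(Q, K, V, c=1.0, mode="exact")   # u = ceil(ln 10) = 3
    u = math.ceil(math.log(10))
    # at least one non-selected row must equal column-mean of V
    vbar = V.mean(axis=0)
    matches = np.isclose(out, vbar, atol=1e-6).all(axis=1).sum()
    assert matches >= 10 - u


def test_single_token_attention_returns_value():
    Q = np.array([[3.0, 1.0]])
    K = np.array([[-1.0, 2.0]])
    V = np.array([[5.0, 7.0]])
    assert np.allclose(sparse_attention(Q, K, V, c=5.0), V)


def test_dense_oracle_properties():
    rng = np.random.default_rng(3)
    Q = rng.normal(size=(4, 3))
    V = rng.normal(size=(1, 3))
    # single key: output equals the value row regardless of the queries
    out = dense_attention_oracle(Q, rng.normal(size=(1, 3)), V)
    assert np.allclose(out, np.broadcast_to(V, out.shape))
    # joint permutation of key/value rows leaves the output unchanged
    K = rng.normal(size=(6, 3))
    V6 = rng.normal(size=(6, 3))
    perm = rng.permutation(6)
    assert np.allclose(dense_attention_oracle(Q, K, V6),
                       dense_attention_oracle(Q, K[perm], V6[perm]))


# ---------------------------------------------------------------------------
# loss / prediction arithmetic
# ---------------------------------------------------------------------------


def test_bce_closed_forms():
    assert abs(bce_loss(np.array([0.5]), np.array([1.0])) - math.log(2)) < 1e-9
    perfect = bce_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0]))
    assert 0 <= perfect <= 1e-6
    v = bce_loss(np.array([0.9, 0.1]), np.array([1.0, 0.0]))
    assert abs(v - (-0.5 * (math.log(0.9) + math.log(0.9)))) < 1e-9
    with pytest.raises(ValueError):
        bce_loss(np.array([0.5]), np.array([1.0, 0.0]))


def test_bce_nonnegative_on_random_inputs():
    for seed in range(30):
        rng = np.random.default_rng(seed)
        y = rng.random(20)
        lab = (rng.random(20) < 0.5).astype(float)
        assert bce_loss(y, lab) >= 0.0


def test_predict_accessibility_sigmoid():
    W = RNG.normal(size=(4, 6))
    y = predict_accessibility(np.zeros(4), W, np.zeros(6))
    assert np.allclose(y, 0.5)
    y_hi = predict_accessibility(np.zeros(4), W, np.full(6, 50.0))
    assert np.all(y_hi > 1 - 1e-9)
    with pytest.raises(ValueError):
        predict_accessibility(np.zeros(3), W, np.zeros(6))


def test_mean_auroc_against_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(5)
    scores = rng.random((50, 4))
    labels = (rng.random((50, 4)) < 0.4).astype(int)
    expected = np.mean([roc_auc_score(labels[:, j], scores[:, j])
                        for j in range(4)])
    assert abs(mean_auroc(scores, labels) - expected) < 1e-12
    # cells without both classes are excluded, not averaged as NaN
    labels[:, 0] = 1
    expected = np.mean([roc_auc_score(labels[:, j], scores[:, j])
                        for j in range(1, 4)])
    assert abs(mean_auroc(scores, labels) - expected) < 1e-12


# ---------------------------------------------------------------------------
# network stages
# ---------------------------------------------------------------------------


def test_stem_plan_long_input_pools_to_threshold():
    cfg = ModelConfig(input_length=131072, n_cells=2, d=8, n_heads=2,
                      stem_threshold=5000, seed=0)
    stages, L_tok = cfg.stem_plan()
    assert (stages, L_tok) == (5, 4096)       # 131072 / 2^5


def test_stem_single_conv_below_threshold():
    cfg = tiny_config(input_length=600, stem_threshold=5000)
    net = M._Network(cfg)
    x = ad.tensor(RNG.random((2, 600, 4)))
    u = net.motif_embedding(x)
    assert u.shape == (2, 600, cfg.d)


def test_stem_pooling_path_shapes_and_finite():
    cfg = tiny_config(input_length=640, stem_threshold=100)
    net = M._Network(cfg)
    u = net.motif_embedding(ad.tensor(np.zeros((1, 640, 4))))
    assert u.shape == (1, 80, cfg.d)          # 640 / 2^3
    assert np.all(np.isfinite(u.data))        # bias-only path stays finite


def test_encoder_layer_halves_tokens_and_is_deterministic():
    cfg = tiny_config(input_length=64, attention_mode="sampled")
    net = M._Network(cfg)
    x = ad.tensor(RNG.random((2, 64, cfg.d)))
    out = net.encoder_layer(x, 0, seed=11, pool=True)
    assert out.shape == (2, 32, cfg.d)
    out2 = net.encoder_layer(x, 0, seed=11, pool=True)
    assert np.array_equal(out.data, out2.data)


def test_encoder_layer_degenerate_weights_reduce_to_ffn_path():
    cfg = tiny_config(input_length=16)
    net = M._Network(cfg)
    p = net.params
    p["enc0_wo"].data[:] = 0.0               # attention contributes nothing
    p["enc0_bo"].data[:] = 0.0
    p["enc0_conv_w"].data[:] = 0.0           # identity convolution
    centre = cfg.enc_kernel // 2
    p["enc0_conv_w"].data[centre] = np.eye(cfg.d)
    p["enc0_conv_b"].data[:] = 0.0
    x = RNG.random((1, 16, cfg.d))
    out = net.encoder_layer(ad.tensor(x), 0, seed=0, pool=True)
    # hand computation: x + FFN(x), then ELU (identity conv), then max pool
    h = x + (np.maximum(x @ p["enc0_ff1_w"].data + p["enc0_ff1_b"].data, 0)
             + np.minimum(np.expm1(x @ p["enc0_ff1_w"].data
                                   + p["enc0_ff1_b"].data), 0)
             ) @ p["enc0_ff2_w"].data + p["enc0_ff2_b"].data
    h = np.where(h > 0, h, np.expm1(h))
    expected = h.reshape(1, 8, 2, cfg.d).max(axis=2)
    assert np.allclose(out.data, expected, atol=1e-10)


def test_sequence_embedding_shape_and_elu_bound():
    cfg = tiny_config(embedding_size=7)
    net = M._Network(cfg)
    z = net.sequence_embedding(ad.tensor(RNG.random((3, 10, cfg.d))))
    assert z.shape == (3, 7)
    assert np.all(z.data > -1.0)             # ELU's open lower bound
    z0 = net.sequence_embedding(ad.tensor(np.zeros((1, 10, cfg.d))))
    for name in ("seq_conv_b", "seq_b"):
        net.params[name].data[:] = 0.0
    z0 = net.sequence_embedding(ad.tensor(np.zeros((1, 10, cfg.d))))
    assert np.allclose(z0.data, 0.0)          # ELU(0) = 0 with zero biases


def test_forward_finite_and_in_open_unit_interval():
    cfg = tiny_config(attention_mode="sampled")
    net = M._Network(cfg)
    for seed in range(100):
        x = np.random.default_rng(seed).random((1, 20, 4))
        y = net.forward(x, seed=seed)
        assert np.all(np.isfinite(y.data))
        assert np.all((y.data > 0) & (y.data < 1))


def test_config_validation():
    with pytest.raises(ValueError, match="even"):
        tiny_config(d=9, n_heads=3)
    with pytest.raises(ValueError, match="divide"):
        tiny_config(d=8, n_heads=3)
    with pytest.raises(ValueError, match=">= 1"):
        tiny_config(c=0.5)
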