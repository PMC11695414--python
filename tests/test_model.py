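"""Core model: attention primitives, encoders, fusion, head, loss and the
parameter/FLOP accounting — each checked against literal double-loop oracles
or hand-derived values."""

import numpy as np
import pytest

from neurofuse import (
    EEGSequence,
    FusionModel,
    LabelSequence,
    ModelConfig,
    PredictionHead,
    ValidationError,
    VideoSequence,
    attention,
    count_parameters,
    estimate_flops,
    knn_mask_attention,
    predict,
    sequence_cross_entropy,
)
from neurofuse.model import flops_breakdown, parameter_shapes

from conftest import random_model_config


# ---------------------------------------------------------------------------
# Independent oracles (literal double loops, no shared code with the package)
# ---------------------------------------------------------------------------


def oracle_attention(q, k, v, scale):
    T = q.shape[0]
    weights = np.zeros((T, k.shape[0]))
    for t in range(T):
        logits = np.array([scale * float(np.dot(q[t], k[j])) for j in range(k.shape[0])])
        e = np.exp(logits - logits.max())
        weights[t] = e / e.sum()
    context = np.zeros((T, v.shape[1]))
    for t in range(T):
        for j in range(v.shape[0]):
            context[t] += weights[t, j] * v[j]
    return context, weights


def oracle_spatial_pool(frame, w_emb, b_emb, pix_pos, u):
    """Per-pixel double loop over one h x w x c frame."""
    h, w, c = frame.shape
    embs, scores = [], []
    p = 0
    for i in range(h):
        for j in range(w):
            e = frame[i, j] @ w_emb + b_emb
            if pix_pos is not None:
                e = e + pix_pos[p]
            embs.append(e)
            scores.append(float(e @ u))
            p += 1
    scores = np.array(scores)
    alpha = np.exp(scores - scores.max())
    alpha /= alpha.sum()
    out = np.zeros_like(embs[0])
    for a, e in zip(alpha, embs):
        out += a * e
    return out


# ---------------------------------------------------------------------------
# attention()
# ---------------------------------------------------------------------------


def test_attention_single_step_is_identity():
    ctx, attn = attention(np.array([[2.0]]), np.array([[-1.0]]), np.array([[7.0, 3.0]]))
    np.testing.assert_array_equal(attn.weights, [[1.0]])
    np.testing.assert_allclose(ctx, [[7.0, 3.0]])


def test_attention_identical_keys_uniform():
    rng = np.random.default_rng(0)
    q = rng.standard_normal((4, 3))
    k = np.tile(rng.standard_normal(3), (4, 1))
    v = rng.standard_normal((4, 2))
    ctx, attn = attention(q, k, v)
    np.testing.assert_allclose(attn.weights, np.full((4, 4), 0.25), atol=1e-14)
    np.testing.assert_allclose(ctx, np.tile(v.mean(axis=0), (4, 1)), atol=1e-14)


def test_attention_hand_derived_two_step():
    # s=1, q=[1;1], keys=[0; ln3], values=[0;1] -> rows [0.25, 0.75], ctx 0.75
    q = np.array([[1.0], [1.0]])
    k = np.array([[0.0], [np.log(3.0)]])
    v = np.array([[0.0], [1.0]])
    ctx, attn = attention(q, k, v, scale_by_sqrt_dim=False)
    np.testing.assert_allclose(attn.weights, [[0.25, 0.75], [0.25, 0.75]], atol=1e-12)
    np.testing.assert_allclose(ctx, [[0.75], [0.75]], atol=1e-12)


@pytest.mark.parametrize("scale_flag", [True, False])
def test_attention_matches_oracle(scale_flag, rng):
    for _ in range(25):
        T, kdim, m = rng.integers(1, 7), rng.integers(1, 5), rng.integers(1, 5)
        q = rng.standard_normal((T, kdim))
        k = rng.standard_normal((T, kdim))
        v = rng.standard_normal((T, m))
        ctx, attn = attention(q, k, v, scale_by_sqrt_dim=scale_flag)
        scale = 1 / np.sqrt(kdim) if scale_flag else 1.0
        octx, ow = oracle_attention(q, k, v, scale)
        np.testing.assert_allclose(ctx, octx, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(attn.weights, ow, rtol=1e-10, atol=1e-12)


def test_attention_rejects_bad_input():
    with pytest.raises(ValidationError):
        attention(np.array([[np.nan]]), np.array([[1.0]]), np.array([[1.0]]))
    with pytest.raises(ValidationError):
        attention(np.empty((0, 2)), np.empty((0, 2)), np.empty((0, 2)))
    with pytest.raises(ValidationError):
        attention(np.ones((2, 2)), np.ones((2, 3)), np.ones((2, 1)))


# ---------------------------------------------------------------------------
# knn_mask_attention()
# ---------------------------------------------------------------------------


def test_knn_k_equals_T_bit_identical(rng):
    logits = rng.standard_normal((5, 5))
    masked = knn_mask_attention(logits, 5).weights
    shifted = logits - logits.max(axis=1, keepdims=True)
    plain = np.exp(shifted) / np.exp(shifted).sum(axis=1, keepdims=True)
    assert np.array_equal(masked, plain)


def test_knn_k1_one_hot(rng):
    logits = rng.standard_normal((6, 6))
    w = knn_mask_attention(logits, 1).weights
    expect = np.zeros_like(logits)
    expect[np.arange(6), logits.argmax(axis=1)] = 1.0
    np.testing.assert_array_equal(w, expect)


def test_knn_hand_row():
    w = knn_mask_attention(np.array([[2.0, 1.0, 0.0]]), 2).weights
    e2, e1 = np.exp(2.0), np.exp(1.0)
    np.testing.assert_allclose(w, [[e2 / (e2 + e1), e1 / (e2 + e1), 0.0]], atol=1e-12)


def test_knn_tie_breaks_to_lower_index():
    w = knn_mask_attention(np.array([[1.0, 1.0, 1.0]]), 2).weights
    np.testing.assert_allclose(w, [[0.5, 0.5, 0.0]], atol=1e-12)


def test_knn_rejects_bad_k():
    with pytest.raises(ValidationError):
        knn_mask_attention(np.zeros((3, 3)), 0)
    with pytest.raises(ValidationError):
        knn_mask_attention(np.zeros((3, 3)), 4)


# ---------------------------------------------------------------------------
# predict() and the loss
# ---------------------------------------------------------------------------


def test_predict_zero_weights_uniform():
    head = PredictionHead(np.zeros((3, 4)), np.zeros(4))
    probs = predict(np.random.default_rng(0).standard_normal((5, 3)), head)
    np.testing.assert_allclose(probs, 0.25, atol=1e-14)


def test_predict_dominant_bias():
    head = PredictionHead(np.zeros((2, 3)), np.array([50.0, 0.0, 0.0]))
    probs = predict(np.zeros((1, 2)), head)
    np.testing.assert_allclose(probs, [[1.0, 0.0, 0.0]], atol=1e-20)


def test_predict_hand_softmax():
    head = PredictionHead(np.eye(2), np.zeros(2))
    probs = predict(np.array([[np.log(3.0), 0.0]]), head)
    np.testing.assert_allclose(probs, [[0.75, 0.25]], atol=1e-12)


def test_loss_zero_on_one_hot():
    probs = np.array([[1.0, 0.0], [0.0, 1.0]])
    y = LabelSequence(np.array([0, 1]), 2)
    assert sequence_cross_entropy(probs, y) == 0.0


def test_loss_uniform_and_half():
    y = LabelSequence(np.array([0, 3]), 4)
    loss = sequence_cross_entropy(np.full((2, 4), 0.25), y)
    np.testing.assert_allclose(loss, 2 * np.log(4), rtol=1e-12)
    y1 = LabelSequence(np.array([1]), 2)
    np.testing.assert_allclose(
        sequence_cross_entropy(np.array([[0.5, 0.5]]), y1), np.log(2), rtol=1e-12
    )


def test_loss_clamps_zero_probability():
    y = LabelSequence(np.array([0]), 2)
    loss = sequence_cross_entropy(np.array([[0.0, 1.0]]), y)
    np.testing.assert_allclose(loss, -np.log(1e-12))


def test_loss_monotone_in_true_class_mass():
    y = LabelSequence(np.array([0]), 2)
    losses = [
        sequence_cross_entropy(np.array([[p, 1 - p]]), y)
        for p in np.linspace(0.05, 0.95, 10)
    ]
    assert all(a > b for a, b in zip(losses, losses[1:]))


# ---------------------------------------------------------------------------
# Encoders and fusion vs. brute-force oracles
# ---------------------------------------------------------------------------


def test_encode_eeg_identity_conv():
    cfg = ModelConfig(
        d=3, h=1, w=1, c=1, h_v=2, d_h=3, d_f=2, n_classes=2,
        conv_kernel=1, dropout_p=0.0, use_positional_encoding=False, max_time=8,
    )
    model = FusionModel(cfg, seed=0)
    model.params["eeg.conv_w"].data = np.eye(3)[None, :, :]
    model.params["eeg.conv_b"].data = np.zeros(3)
    x = np.abs(np.random.default_rng(0).standard_normal((5, 3))) + 3.0
    h, _, _ = model.encode_eeg(EEGSequence(x))
    # gelu(x) ~ x for large positive x; check the linear part via gelu inverse-free bound
    from scipy.special import erf

    expect = x * 0.5 * (1 + erf(x / np.sqrt(2)))
    np.testing.assert_allclose(h.values, expect, rtol=1e-12)


def test_encode_eeg_constant_input_uniform_context(tiny_cfg):
    # kernel 1 so the same-padding conv cannot break time symmetry at edges
    model = FusionModel(ModelConfig(**{**tiny_cfg.__dict__, "conv_kernel": 1}), seed=1)
    x = np.tile(np.array([0.3, -0.2, 1.0]), (6, 1))
    h, ctx, attn = model.encode_eeg(EEGSequence(x))
    np.testing.assert_allclose(attn.weights, 1.0 / 6, atol=1e-14)
    for t in range(6):
        np.testing.assert_allclose(ctx[t], h.values[0], rtol=1e-10, atol=1e-12)


def test_encode_eeg_matches_double_loop(tiny_cfg, rng):
    model = FusionModel(tiny_cfg, seed=2)
    x = rng.standard_normal((4, 3))
    h, ctx, attn = model.encode_eeg(EEGSequence(x))
    q = h.values @ model.params["eeg.wq"].data
    k = h.values @ model.params["eeg.wk"].data
    octx, ow = oracle_attention(q, k, h.values, 1 / np.sqrt(tiny_cfg.d_h))
    np.testing.assert_allclose(ctx, octx, rtol=1e-10, atol=1e-13)
    np.testing.assert_allclose(attn.weights, ow, rtol=1e-10, atol=1e-13)


def test_encode_eeg_rejects_wrong_channels(tiny_cfg):
    model = FusionModel(tiny_cfg, seed=0)
    with pytest.raises(ValidationError):
        model.encode_eeg(EEGSequence(np.ones((4, 7))))


def test_video_single_pixel_returns_embedding(tiny_cfg):
    cfg = tiny_cfg
    cfg = ModelConfig(**{**cfg.__dict__, "h": 1, "w": 1})
    model = FusionModel(cfg, seed=3)
    frames = np.random.default_rng(0).standard_normal((3, 1, 1, 1))
    h, _, _ = model.encode_video(VideoSequence(frames=frames))
    expect = (
        frames.reshape(3, 1) @ model.params["video.embed_w"].data
        + model.params["video.embed_b"].data
    )
    np.testing.assert_allclose(h.values, expect, rtol=1e-12)


def test_video_constant_frame_uniform_spatial(tiny_cfg):
    model = FusionModel(tiny_cfg, seed=4)
    frames = np.full((2, 2, 2, 1), 0.7)
    h, _, _ = model.encode_video(VideoSequence(frames=frames))
    one_pixel = (
        np.array([0.7]) @ model.params["video.embed_w"].data
        + model.params["video.embed_b"].data
    )
    for t in range(2):
        np.testing.assert_allclose(h.values[t], one_pixel, rtol=1e-12)


@pytest.mark.parametrize("use_pos", [False, True])
def test_encode_video_matches_per_pixel_oracle(use_pos, tiny_cfg, rng):
    cfg = ModelConfig(**{**tiny_cfg.__dict__, "use_positional_encoding": use_pos})
    model = FusionModel(cfg, seed=5)
    frames = rng.standard_normal((3, 2, 2, 1))
    h, ctx, attn = model.encode_video(VideoSequence(frames=frames))
    pix_pos = model.params["video.pix_pos"].data if use_pos else None
    pooled = np.stack(
        [
            oracle_spatial_pool(
                frames[t],
                model.params["video.embed_w"].data,
                model.params["video.embed_b"].data,
                pix_pos,
                model.params["video.score"].data[:, 0],
            )
            for t in range(3)
        ]
    )
    if use_pos:
        pooled = pooled + model.params["video.pos"].data[:3]
    np.testing.assert_allclose(h.values, pooled, rtol=1e-10, atol=1e-12)
    q = pooled @ model.params["video.wq"].data
    k = pooled @ model.params["video.wk"].data
    octx, ow = oracle_attention(q, k, pooled, 1 / np.sqrt(cfg.h_v))
    np.testing.assert_allclose(ctx, octx, rtol=1e-10, atol=1e-12)
    np.testing.assert_allclose(attn.weights, ow, rtol=1e-10, atol=1e-12)


def test_video_prefeaturized_skips_spatial(tiny_cfg):
    model = FusionModel(tiny_cfg, seed=6)
    feats = np.random.default_rng(1).standard_normal((4, tiny_cfg.h_v))
    h, _, _ = model.encode_video(VideoSequence(features=feats))
    np.testing.assert_array_equal(h.values, feats)


def test_video_rejects_mixed_input():
    with pytest.raises(ValidationError):
        VideoSequence(frames=np.ones((2, 2, 2, 1)), features=np.ones((2, 3)))
    with pytest.raises(ValidationError):
        VideoSequence()


def test_cross_modal_fuse_single_step(tiny_cfg):
    model = FusionModel(tiny_cfg, seed=7)
    pe = np.array([[0.4, -1.0, 2.0]])
    pv = np.array([[1.0, 0.5, -0.5]])
    cross, attn = model.cross_modal_fuse(pe, pv)
    np.testing.assert_array_equal(attn.weights, [[1.0]])
    np.testing.assert_allclose(cross, pe + pv, rtol=1e-14)


def test_cross_modal_fuse_identical_video_rows_uniform(tiny_cfg, rng):
    model = FusionModel(tiny_cfg, seed=8)
    pe = rng.standard_normal((4, 3))
    pv = np.tile(rng.standard_normal(3), (4, 1))
    cross, attn = model.cross_modal_fuse(pe, pv)
    np.testing.assert_allclose(attn.weights, 0.25, atol=1e-14)
    np.testing.assert_allclose(
        cross, np.tile((pe + pv).mean(axis=0), (4, 1)), rtol=1e-10, atol=1e-12
    )


def test_cross_modal_fuse_matches_double_loop(tiny_cfg, rng):
    model = FusionModel(tiny_cfg, seed=9)
    T, d_f = 3, tiny_cfg.d_f
    pe = rng.standard_normal((T, d_f))
    pv = rng.standard_normal((T, d_f))
    cross, attn = model.cross_modal_fuse(pe, pv)
    scale = 1 / np.sqrt(d_f)
    expect = np.zeros_like(pe)
    for t in range(T):
        logits = np.array([scale * pe[t] @ pv[j] for j in range(T)])
        w = np.exp(logits - logits.max())
        w /= w.sum()
        for j in range(T):
            expect[t] += w[j] * (pe[j] + pv[j])
        np.testing.assert_allclose(attn.weights[t], w, rtol=1e-12)
    np.testing.assert_allclose(cross, expect, rtol=1e-12, atol=1e-13)


def test_cross_modal_fuse_rejects_width_mismatch(tiny_cfg):
    model = FusionModel(tiny_cfg, seed=0)
    with pytest.raises(ValidationError):
        model.cross_modal_fuse(np.ones((3, 2)), np.ones((3, 3)))


# ---------------------------------------------------------------------------
# Invariants
# ---------------------------------------------------------------------------


def test_attention_rows_stochastic_100_trials():
    rng = np.random.default_rng(99)
    for _ in range(100):
        T = int(rng.integers(1, 8))
        q = rng.standard_normal((T, 3)) * rng.uniform(0.1, 5)
        k = rng.standard_normal((T, 3)) * rng.uniform(0.1, 5)
        v = rng.standard_normal((T, 2))
        _, attn = attention(q, k, v)
        w = attn.weights
        assert np.all(w >= 0) and np.all(w <= 1)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-8)


def test_permutation_equivariance_of_attention(rng):
    T = 6
    q = rng.standard_normal((T, 4))
    k = rng.standard_normal((T, 4))
    v = rng.standard_normal((T, 3))
    perm = rng.permutation(T)
    ctx, _ = attention(q, k, v)
    ctx_p, _ = attention(q[perm], k[perm], v[perm])
    np.testing.assert_allclose(ctx_p, ctx[perm], rtol=1e-12)


def test_model_knn_flag_changes_attention(tiny_cfg, rng):
    cfg = ModelConfig(**{**tiny_cfg.__dict__, "use_knn_attention": True, "knn_k": 2})
    model = FusionModel(cfg, seed=11)
    x = rng.standard_normal((5, 3))
    _, _, attn = model.encode_eeg(EEGSequence(x))
    assert np.all((attn.weights > 0).sum(axis=1) == 2)
    np.testing.assert_allclose(attn.weights.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# Parameter and FLOP accounting
# ---------------------------------------------------------------------------


def test_head_only_counts():
    cfg = ModelConfig(d_f=2, n_classes=3)
    shapes = parameter_shapes(cfg)
    assert int(np.prod(shapes["head.w"])) + int(np.prod(shapes["head.b"])) == 9
    assert flops_breakdown(cfg, T=1)["head"] == 6


def test_count_parameters_linear_in_classes(tiny_cfg):
    base = count_parameters(tiny_cfg)
    doubled = count_parameters(
        ModelConfig(**{**tiny_cfg.__dict__, "n_classes": 2 * tiny_cfg.n_classes})
    )
    assert doubled - base == tiny_cfg.d_f * tiny_cfg.n_classes + tiny_cfg.n_classes


def test_count_parameters_matches_container_walk():
    rng = np.random.default_rng(7)
    for _ in range(20):
        cfg = random_model_config(rng)
        variant = str(rng.choice(["full", "no_eeg_stream"]))
        model = FusionModel(cfg, seed=int(rng.integers(100)), variant=variant)
        walked = sum(p.data.size for p in model.parameters().values())
        assert count_parameters(cfg, variant) == walked


def test_flops_scaling_with_T(tiny_cfg):
    b1 = flops_breakdown(tiny_cfg, T=4)
    b2 = flops_breakdown(tiny_cfg, T=8)
    for key in b1:
        if "attention" in key:
            assert b2[key] == 4 * b1[key]
        else:
            assert b2[key] == 2 * b1[key]
    assert estimate_flops(tiny_cfg, 4) == sum(b1.values())


def test_flops_hand_sum():
    cfg = ModelConfig(
        d=2, h=2, w=2, c=1, h_v=3, d_h=4, d_f=5, n_classes=2,
        conv_kernel=3, use_positional_encoding=False, dropout_p=0.0,
    )
    T = 4
    hand = (
        T * 2 * 4 * 3  # conv
        + 2 * T * 4 * 4 + 2 * T * T * 4  # eeg q/k + attention
        + T * 4 * 1 * 3 + 2 * T * 4 * 3  # spatial (P=4) embed + score/pool
        + 2 * T * 3 * 3 + 2 * T * T * 3  # video q/k + attention
        + T * 4 * 5 + T * 3 * 5  # fusion projections
        + 2 * T * T * 5  # cross attention
        + T * 5 * 2  # head
    )
    assert estimate_flops(cfg, T) == hand


# ---------------------------------------------------------------------------
# Type validation
# ---------------------------------------------------------------------------


def test_type_invariants():
    with pytest.raises(ValidationError):
        EEGSequence(np.array([[np.inf, 1.0]]))
    with pytest.raises(ValidationError):
        LabelSequence(np.array([0, 2]), n_classes=2)
    with pytest.raises(ValidationError):
        ModelConfig(conv_kernel=2)
    with pytest.raises(ValidationError):
        ModelConfig(dropout_p=1.0)
    from neurofuse.model import AttentionMatrix

    with pytest.raises(ValidationError):
        AttentionMatrix(np.array([[0.5, 0.4], [0.5, 0.5]]))


def test_describe_bundle(tiny_cfg, rng):
    model = FusionModel(tiny_cfg, seed=13)
    eeg = EEGSequence(rng.standard_normal((4, 3)))
    video = VideoSequence(frames=rng.standard_normal((4, 2, 2, 1)))
    bundle = model.describe(eeg, video)
    assert bundle.eeg_context.shape == (4, tiny_cfg.d_h)
    assert bundle.video_context.shape == (4, tiny_cfg.h_v)
    assert bundle.cross_context.shape == (4, tiny_cfg.d_f)
    np.testing.assert_allclose(bundle.attn_cross.weights.sum(axis=1), 1.0, atol=1e-8)


def test_describe_no_eeg_variant(tiny_cfg, rng):
    model = FusionModel(tiny_cfg, seed=14, variant="no_eeg_stream")
    video = VideoSequence(frames=rng.standard_normal((3, 2, 2, 1)))
    bundle = model.describe(None, video)
    assert bundle.eeg_context is None and bundle.attn_cross is None
    assert bundle.cross_context.shape == (3, tiny_cfg.d_f)
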