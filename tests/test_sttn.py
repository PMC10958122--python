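"""Transformer generator: attention algebra, a brute-force reference
implementation of the full transformer stack, clip inpainting and
checkpoint round-trips."""

import numpy as np
import pytest

from endoinpaint.autodiff import Tensor
from endoinpaint.sttn import (DiscriminatorState, GeneratorState,
                              TransformerConfig, attend, attention_weights,
                              discriminator_score, downsample_mask,
                              encode_frames, extract_patches, fold_patches,
                              generator_forward, inpaint_clip, load_checkpoint,
                              patch_similarity, patch_validity,
                              save_checkpoint, transformer_forward,
                              window_indices)


# -- config ---------------------------------------------------------------


def test_head_patch_sizes_must_divide_feature_map():
    with pytest.raises(ValueError):
        TransformerConfig(input_size=(64, 64), channels=32,
                          heads=[(8, 8), (5, 5)], base_channels=16, layers=1)


def test_channels_must_split_across_heads():
    with pytest.raises(ValueError):
        TransformerConfig(input_size=(64, 64), channels=30,
                          heads=[(8, 8), (4, 4), (2, 2), (16, 16)],
                          base_channels=16, layers=1)


# -- patch bookkeeping ----------------------------------------------------


def test_extract_fold_roundtrip():
    rng = np.random.default_rng(0)
    f = Tensor(rng.normal(size=(3, 4, 8, 8)))
    p = extract_patches(f, 4, 2)
    assert p.shape == (3 * 2 * 4, 4 * 4 * 2)
    back = fold_patches(p, 3, 4, 8, 8, 4, 2)
    assert np.array_equal(back.data, f.data)


def test_patch_validity_flags_any_hole_overlap():
    m = np.zeros((1, 8, 8))
    m[0, 0, 0] = 1  # one hole pixel in the top-left 4x4 patch
    v = patch_validity(m, 4, 4)
    assert v.tolist() == [0.0, 1.0, 1.0, 1.0]


def test_downsample_mask_is_block_max():
    m = np.zeros((1, 8, 8))
    m[0, 5, 2] = 1
    d = downsample_mask(m, 4)
    assert d.shape == (1, 2, 2)
    assert d[0].tolist() == [[0, 0], [1, 0]]


# -- the three attention equations ----------------------------------------


def test_patch_similarity_is_scaled_dot_product():
    rng = np.random.default_rng(1)
    r1, r2, c = 3, 2, 4
    a, b = rng.normal(size=(2, r1 * r2 * c))
    got = patch_similarity(a, b, r1, r2, c)
    assert got == pytest.approx(float(a @ b) / (r1 * r2 * c), abs=1e-12)


def test_attention_rows_sum_to_one_over_valid_patches():
    rng = np.random.default_rng(2)
    s = rng.normal(size=(10, 12)) * 5
    valid = (rng.random(12) > 0.4).astype(float)
    assert valid.sum() > 0
    w, degen = attention_weights(s, valid)
    assert not degen.any()
    assert np.abs(w.sum(axis=1) - 1.0).max() <= 1e-6
    assert (w[:, valid == 0] == 0).all()
    assert (w >= 0).all()


def test_attention_degenerate_when_no_valid_patch():
    w, degen = attention_weights(np.array([1.0, 2.0, 3.0]), np.zeros(3))
    assert degen
    assert (w == 0).all()


def test_attention_matches_manual_two_patch_softmax():
    s = np.array([0.0, np.log(3.0), 100.0])
    valid = np.array([1.0, 1.0, 0.0])
    w, _ = attention_weights(s, valid)
    assert w == pytest.approx([0.25, 0.75, 0.0], abs=1e-12)


def test_attend_is_weighted_sum():
    w = np.array([[0.25, 0.75]])
    v = np.array([[1.0, 2.0], [3.0, 6.0]])
    assert np.allclose(attend(w, v), [[2.5, 5.0]])


# -- brute-force reference transformer ------------------------------------


def _naive_conv2d(x, w, b, stride, pad):
    T, C, H, W = x.shape
    O, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    out = np.zeros((T, O, Ho, Wo))
    for t in range(T):
        for o in range(O):
            for i in range(Ho):
                for j in range(Wo):
                    win = xp[t, :, i * stride:i * stride + kh,
                             j * stride:j * stride + kw]
                    out[t, o, i, j] = (win * w[o]).sum() + b[o]
    return out


def _naive_extract(f, r1, r2):
    t, c, h, w = f.shape
    rows = []
    for ti in range(t):
        for bi in range(h // r1):
            for bj in range(w // r2):
                blk = f[ti, :, bi * r1:(bi + 1) * r1, bj * r2:(bj + 1) * r2]
                rows.append(blk.reshape(-1))
    return np.stack(rows)


def _naive_fold(p, t, c, h, w, r1, r2):
    out = np.zeros((t, c, h, w))
    k = 0
    for ti in range(t):
        for bi in range(h // r1):
            for bj in range(w // r2):
                out[ti, :, bi * r1:(bi + 1) * r1, bj * r2:(bj + 1) * r2] = (
                    p[k].reshape(c, r1, r2)
                )
                k += 1
    return out


def _reference_transformer(features, masks, config, state):
    """Unbatched pure-numpy re-derivation of the transformer stack."""
    p = {k: v.data for k, v in state.params.items()}
    t, C, h, w = features.shape
    hc = config.head_channels
    m_small = downsample_mask(np.asarray(masks, float), config.downsample)
    f = features.copy()
    for L in range(config.layers):
        heads_out = []
        for hd, (r1, r2) in enumerate(config.heads):
            q = _naive_conv2d(f, p[f"l{L}.h{hd}.q.w"], p[f"l{L}.h{hd}.q.b"], 1, 0)
            k = _naive_conv2d(f, p[f"l{L}.h{hd}.k.w"], p[f"l{L}.h{hd}.k.b"], 1, 0)
            v = _naive_conv2d(f, p[f"l{L}.h{hd}.v.w"], p[f"l{L}.h{hd}.v.b"], 1, 0)
            pq, pk, pv = (_naive_extract(x, r1, r2) for x in (q, k, v))
            n = pq.shape[0]
            valid = np.zeros(n)
            blocks = m_small.reshape(t, h // r1, r1, w // r2, r2).max(axis=(2, 4))
            valid = (blocks.reshape(-1) == 0).astype(float)
            s = np.empty((n, n))
            for i in range(n):
                for j in range(n):
                    s[i, j] = patch_similarity(pq[i], pk[j], r1, r2, hc)
            alpha, _ = attention_weights(s, valid)
            o = attend(alpha, pv)
            if valid.sum() == 0:
                o = o + pv
            heads_out.append(_naive_fold(o, t, hc, h, w, r1, r2))
        cat = np.concatenate(heads_out, axis=1)
        z = np.maximum(0.0, _naive_conv2d(cat, p[f"l{L}.fuse1.w"],
                                          p[f"l{L}.fuse1.b"], 1, 1))
        z = _naive_conv2d(z, p[f"l{L}.fuse2.w"], p[f"l{L}.fuse2.b"], 1, 1)
        f = f + z
    return f


def test_transformer_matches_brute_force_reference():
    config = TransformerConfig.tiny((32, 32))
    state = GeneratorState(config, seed=3)
    rng = np.random.default_rng(4)
    frames = rng.random(size=(3, 32, 32, 3))
    masks = np.zeros((3, 32, 32))
    masks[0, 4:14, 6:20] = 1
    masks[1, 20:30, 2:12] = 1
    x = (frames * 2 - 1) * (1.0 - masks[..., None])
    feats = encode_frames(x, masks, state)
    got = transformer_forward(feats, masks, config, state).data
    ref = _reference_transformer(feats.data, masks, config, state)
    scale = max(1.0, np.abs(ref).max())
    assert np.abs(got - ref).max() / scale <= 1e-5


def test_transformer_finite_when_every_patch_is_a_hole():
    config = TransformerConfig.tiny((32, 32))
    state = GeneratorState(config, seed=3)
    frames = np.random.default_rng(5).random(size=(2, 32, 32, 3))
    masks = np.ones((2, 32, 32))
    out = generator_forward(frames, masks, state, config)
    assert np.isfinite(out.data).all()


# -- clip inpainting ------------------------------------------------------


def test_window_indices_neighbours_plus_distant():
    assert window_indices(30, [12, 13, 14], 2, 10) == [0, 10, 11, 12, 13, 14, 15, 16, 20]
    assert window_indices(5, [0], 2, 10) == [0, 1, 2]


def test_inpaint_preserves_valid_pixels_bit_exactly(tiny_clip):
    clean, masks, corrupted = tiny_clip
    config = TransformerConfig.tiny()
    state = GeneratorState(config, seed=0)
    out = inpaint_clip(corrupted, masks, state, config)
    assert out.shape == corrupted.shape
    valid = masks == 0
    assert np.array_equal(out[valid], corrupted[valid])
    assert (out >= 0).all() and (out <= 1).all()


def test_inpaint_deterministic_given_state(tiny_clip):
    _, masks, corrupted = tiny_clip
    config = TransformerConfig.tiny()
    state = GeneratorState(config, seed=0)
    a = inpaint_clip(corrupted, masks, state, config)
    b = inpaint_clip(corrupted, masks, state, config)
    assert np.array_equal(a, b)


def test_empty_clip_rejected():
    config = TransformerConfig.tiny()
    state = GeneratorState(config, seed=0)
    with pytest.raises(ValueError):
        inpaint_clip(np.zeros((0, 64, 64, 3)), np.zeros((0, 64, 64)), state)


# -- discriminator --------------------------------------------------------


def test_discriminator_scores_shape_and_short_clip_error():
    dstate = DiscriminatorState(seed=1)
    clip = np.random.default_rng(6).random(size=(5, 32, 32, 3))
    scores = discriminator_score(clip, dstate)
    assert scores.shape[0] == 5 - (DiscriminatorState.RECEPTIVE_T - 1)
    with pytest.raises(ValueError):
        discriminator_score(clip[:2], dstate)


# -- checkpoints ----------------------------------------------------------


def test_checkpoint_roundtrip_is_bit_exact(tmp_path):
    config = TransformerConfig.tiny()
    state = GeneratorState(config, seed=9)
    dstate = DiscriminatorState(seed=4)
    path = tmp_path / "ck.npz"
    save_checkpoint(path, state, dstate, extra={"iteration": 7})
    s2, d2, header = load_checkpoint(path)
    assert header["iteration"] == 7
    assert s2.config == config
    for k in state.params:
        assert np.array_equal(s2.params[k].data, state.params[k].data)
    for k in dstate.params:
        assert np.array_equal(d2.params[k].data, dstate.params[k].data)
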