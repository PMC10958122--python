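"""Spatial–temporal transformer generator and temporal patch discriminator.

The generator inpaints hole regions of a video by attending jointly over
spatial patches of all frames in a window: a frame-level convolutional
encoder produces feature maps, a stack of multi-head transformer layers
matches query patches against key patches drawn from the *valid* (hole-free)
region of every frame and aggregates the corresponding value patches, and a
convolutional decoder maps the fused features back to image space.  Each
head runs the same attention at a different patch scale, so coarse heads
borrow large background patches from other frames while fine heads recover
detail.  The discriminator is a 3D-convolutional patch critic in the
T-PatchGAN style, scoring spatio-temporal patches with unbounded real
values for use with hinge losses.

Conventions: clips are float arrays of shape (T, H, W, 3) with values in
[0, 1]; masks are (T, H, W) with 1 = hole (to inpaint), 0 = valid.  The
generator internally normalises frames to [-1, 1] and always computes the
masked input X = Y * (1 - M) itself.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concatenate, conv2d, conv3d, upsample_nearest2d

__all__ = [
    "TransformerConfig",
    "GeneratorState",
    "DiscriminatorState",
    "encode_frames",
    "patch_similarity",
    "attention_weights",
    "attend",
    "transformer_forward",
    "generator_forward",
    "inpaint_clip",
    "discriminator_score",
    "extract_patches",
    "fold_patches",
    "patch_validity",
    "downsample_mask",
]


@dataclass
class TransformerConfig:
    """Architecture hyper-parameters.

    ``heads`` lists one spatial patch size (r1, r2) per attention head; every
    entry must divide the encoded feature-map size exactly.  ``neighbor_window``
    (n) and ``distant_rate`` (s) control which frames condition each target
    window: neighbours t-n..t+n plus distant frames sampled every s frames.
    """

    input_size: tuple = (288, 288)
    base_channels: int = 64
    channels: int = 256
    layers: int = 8
    heads: list = field(default_factory=lambda: [(72, 72), (36, 36), (18, 18), (9, 9)])
    neighbor_window: int = 2
    distant_rate: int = 10
    downsample: int = 4  # encoder stride product; feature map = input / downsample

    def __post_init__(self):
        h, w = self.feature_map_size
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if self.neighbor_window < 0 or self.distant_rate < 1:
            raise ValueError("neighbor_window >= 0 and distant_rate >= 1 required")
        if self.channels % len(self.heads) != 0:
            raise ValueError("channels must split evenly across heads")
        for r1, r2 in self.heads:
            if h % r1 or w % r2:
                raise ValueError(
                    f"patch size ({r1},{r2}) does not divide feature map ({h},{w})"
                )

    @property
    def feature_map_size(self) -> tuple:
        return (self.input_size[0] // self.downsample, self.input_size[1] // self.downsample)

    @property
    def head_channels(self) -> int:
        return self.channels // len(self.heads)

    @classmethod
    def tiny(cls, input_size=(64, 64)) -> "TransformerConfig":
        """Desk-scale configuration used throughout the test suite."""
        return cls(
            input_size=input_size,
            base_channels=16,
            channels=32,
            layers=1,
            heads=[(8, 8), (4, 4)],
            neighbor_window=2,
            distant_rate=10,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["heads"] = [list(h) for h in self.heads]
        d["input_size"] = list(self.input_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TransformerConfig":
        d = dict(d)
        d["heads"] = [tuple(h) for h in d["heads"]]
        d["input_size"] = tuple(d["input_size"])
        return cls(**d)


def _init_conv(rng, out_c, in_c, kh, kw):
    fan_in = in_c * kh * kw
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_c, in_c, kh, kw))
    return Tensor(w, requires_grad=True), Tensor(np.zeros(out_c), requires_grad=True)


class GeneratorState:
    """All generator parameters, keyed by name, with an explicit init seed."""

    def __init__(self, config: TransformerConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        p = {}
        b = config.base_channels
        C = config.channels
        hc = config.head_channels
        p["enc1.w"], p["enc1.b"] = _init_conv(rng, b, 4, 3, 3)
        p["enc2.w"], p["enc2.b"] = _init_conv(rng, b, b, 3, 3)
        p["enc3.w"], p["enc3.b"] = _init_conv(rng, C, b, 3, 3)
        for L in range(config.layers):
            for hd in range(len(config.heads)):
                for nm in ("q", "k", "v"):
                    p[f"l{L}.h{hd}.{nm}.w"], p[f"l{L}.h{hd}.{nm}.b"] = _init_conv(
                        rng, hc, C, 1, 1
                    )
            p[f"l{L}.fuse1.w"], p[f"l{L}.fuse1.b"] = _init_conv(rng, C, C, 3, 3)
            p[f"l{L}.fuse2.w"], p[f"l{L}.fuse2.b"] = _init_conv(rng, C, C, 3, 3)
        p["dec1.w"], p["dec1.b"] = _init_conv(rng, b, C, 3, 3)
        p["dec2.w"], p["dec2.b"] = _init_conv(rng, b, b, 3, 3)
        p["dec3.w"], p["dec3.b"] = _init_conv(rng, 3, b, 3, 3)
        self.params = p

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.params.values())

    def zero_grad(self):
        for t in self.params.values():
            t.grad = None


class DiscriminatorState:
    """3D-convolutional patch critic parameters (T-PatchGAN style)."""

    RECEPTIVE_T = 3  # final temporal conv is unpadded

    def __init__(self, base_channels: int = 16, seed: int = 0):
        self.base_channels = int(base_channels)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        d = self.base_channels

        def init3(out_c, in_c, kt, kh, kw):
            fan_in = in_c * kt * kh * kw
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_c, in_c, kt, kh, kw))
            return Tensor(w, requires_grad=True), Tensor(np.zeros(out_c), requires_grad=True)

        p = {}
        p["d1.w"], p["d1.b"] = init3(d, 3, 3, 5, 5)
        p["d2.w"], p["d2.b"] = init3(2 * d, d, 3, 5, 5)
        p["d3.w"], p["d3.b"] = init3(2 * d, 2 * d, 3, 5, 5)
        p["d4.w"], p["d4.b"] = init3(1, 2 * d, 3, 5, 5)
        self.params = p

    def zero_grad(self):
        for t in self.params.values():
            t.grad = None


# -- patch bookkeeping ----------------------------------------------------


def downsample_mask(masks: np.ndarray, factor: int) -> np.ndarray:
    """Block-maximum downsampling: a feature cell is a hole if any pixel is."""
    t, h, w = masks.shape
    return masks.reshape(t, h // factor, factor, w // factor, factor).max(axis=(2, 4))


def extract_patches(f: Tensor, r1: int, r2: int) -> Tensor:
    """(T, C, h, w) -> (N, r1*r2*C) with N = T * h/r1 * w/r2."""
    t, c, h, w = f.shape
    g = f.reshape(t, c, h // r1, r1, w // r2, r2)
    g = g.transpose(0, 2, 4, 1, 3, 5)
    return g.reshape(t * (h // r1) * (w // r2), c * r1 * r2)


def fold_patches(p: Tensor, t: int, c: int, h: int, w: int, r1: int, r2: int) -> Tensor:
    """Inverse of :func:`extract_patches`."""
    g = p.reshape(t, h // r1, w // r2, c, r1, r2)
    g = g.transpose(0, 3, 1, 4, 2, 5)
    return g.reshape(t, c, h, w)


def patch_validity(mask_small: np.ndarray, r1: int, r2: int) -> np.ndarray:
    """Per-patch validity flags: a patch is invalid iff it intersects the hole."""
    t, h, w = mask_small.shape
    blocks = mask_small.reshape(t, h // r1, r1, w // r2, r2).max(axis=(2, 4))
    return (blocks.reshape(-1) == 0).astype(np.float64)


# -- the three attention steps (reference-grade scalar/row forms) ---------


def patch_similarity(p_q: np.ndarray, p_k: np.ndarray, r1: int, r2: int, c: int) -> float:
    """Scaled dot product between one query and one key patch vector."""
    p_q = np.asarray(p_q, dtype=float).ravel()
    p_k = np.asarray(p_k, dtype=float).ravel()
    if p_q.shape != p_k.shape or p_q.size != r1 * r2 * c:
        raise ValueError("patch vectors must both have length r1*r2*c")
    return float(p_q @ p_k) / (r1 * r2 * c)


def attention_weights(similarities: np.ndarray, validity: np.ndarray):
    """Masked softmax over valid patches for one (or many stacked) query rows.

    Invalid entries receive weight exactly 0 and are excluded from the
    denominator.  Returns ``(weights, degenerate)`` where ``degenerate`` flags
    rows with no valid patch at all (those rows are all-zero).
    """
    s = np.asarray(similarities, dtype=float)
    if np.isnan(s).any():
        raise ValueError("NaN similarity")
    v = np.asarray(validity, dtype=float)
    squeeze = s.ndim == 1
    s2 = np.atleast_2d(s)
    vrow = np.broadcast_to(v, s2.shape)
    degenerate = vrow.sum(axis=1) == 0
    smax = np.where(vrow > 0, s2, -np.inf).max(axis=1, keepdims=True)
    smax = np.where(np.isfinite(smax), smax, 0.0)
    e = np.exp(s2 - smax) * vrow
    den = e.sum(axis=1, keepdims=True)
    den[den == 0] = 1.0
    w = e / den
    if squeeze:
        return w[0], bool(degenerate[0])
    return w, degenerate


def attend(weights: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Weighted sum of value patches: o_i = sum_j alpha_ij p_j^v."""
    w = np.asarray(weights, dtype=float)
    v = np.asarray(values, dtype=float)
    if w.shape[-1] != v.shape[0]:
        raise ValueError("weights/value count mismatch")
    return w @ v


# -- generator forward path ----------------------------------------------


def encode_frames(masked_frames: np.ndarray, masks: np.ndarray, state: GeneratorState) -> Tensor:
    """Frame-level encoder: (T,H,W,3) in [-1,1] + (T,H,W) masks -> (T,C,h,w).

    The mask is stacked as a fourth input channel so downstream layers know
    which pixels carry no information.  Frames are processed independently.
    """
    if masked_frames.shape[:3] != masks.shape:
        raise ValueError("frame/mask shape mismatch")
    p = state.params
    x = np.concatenate(
        [masked_frames.transpose(0, 3, 1, 2), masks[:, None, :, :]], axis=1
    )
    t = Tensor(x)
    t = conv2d(t, p["enc1.w"], p["enc1.b"], stride=1, padding=1).relu()
    t = conv2d(t, p["enc2.w"], p["enc2.b"], stride=2, padding=1).relu()
    t = conv2d(t, p["enc3.w"], p["enc3.b"], stride=2, padding=1).relu()
    return t


def _attention_head(f: Tensor, masks_small: np.ndarray, state, layer: int, head: int,
                    r1: int, r2: int) -> Tensor:
    p = state.params
    t, C, h, w = f.shape
    hc = state.config.head_channels
    q = conv2d(f, p[f"l{layer}.h{head}.q.w"], p[f"l{layer}.h{head}.q.b"], 1, 0)
    k = conv2d(f, p[f"l{layer}.h{head}.k.w"], p[f"l{layer}.h{head}.k.b"], 1, 0)
    v = conv2d(f, p[f"l{layer}.h{head}.v.w"], p[f"l{layer}.h{head}.v.b"], 1, 0)
    pq = extract_patches(q, r1, r2)
    pk = extract_patches(k, r1, r2)
    pv = extract_patches(v, r1, r2)
    valid = patch_validity(masks_small, r1, r2)  # (N,)
    s = pq @ pk.transpose(1, 0) * (1.0 / (r1 * r2 * hc))
    # numerically stabilised masked softmax over valid keys
    sdata = s.data
    vmask = valid[None, :]
    smax = np.where(vmask > 0, sdata, -np.inf).max(axis=1, keepdims=True)
    smax = np.where(np.isfinite(smax), smax, 0.0)
    e = (s - Tensor(smax)).exp() * Tensor(vmask)
    den = e.sum(axis=1, keepdims=True)
    den_safe = den + Tensor((den.data == 0).astype(float))
    alpha = e / den_safe
    o = alpha @ pv
    if valid.sum() == 0:
        # degenerate: no valid patch anywhere -> pass the (value-embedded)
        # encoder feature of each query location through unchanged
        o = o + pv
    return fold_patches(o, t, hc, h, w, r1, r2)


def transformer_forward(features: Tensor, masks: np.ndarray, config: TransformerConfig,
                        state: GeneratorState) -> Tensor:
    """Multi-layer multi-head attention with residual fusion.

    Per layer and head: 1x1 embeddings -> patch extraction -> scaled
    dot-product similarity -> masked softmax over valid patches -> weighted
    value aggregation -> fold; head outputs are concatenated channel-wise and
    passed through a small residual convolution block.
    """
    p = state.params
    factor = config.downsample
    masks_small = downsample_mask(np.asarray(masks, dtype=float), factor)
    f = features
    for L in range(config.layers):
        outs = [
            _attention_head(f, masks_small, state, L, hd, r1, r2)
            for hd, (r1, r2) in enumerate(config.heads)
        ]
        cat = concatenate(outs, axis=1)
        z = conv2d(cat, p[f"l{L}.fuse1.w"], p[f"l{L}.fuse1.b"], 1, 1).relu()
        z = conv2d(z, p[f"l{L}.fuse2.w"], p[f"l{L}.fuse2.b"], 1, 1)
        f = f + z
    return f


def _decode(f: Tensor, state: GeneratorState) -> Tensor:
    p = state.params
    t = upsample_nearest2d(f, 2)
    t = conv2d(t, p["dec1.w"], p["dec1.b"], 1, 1).relu()
    t = upsample_nearest2d(t, 2)
    t = conv2d(t, p["dec2.w"], p["dec2.b"], 1, 1).relu()
    t = conv2d(t, p["dec3.w"], p["dec3.b"], 1, 1)
    return t.tanh()


def generator_forward(frames: np.ndarray, masks: np.ndarray, state: GeneratorState,
                      config: TransformerConfig | None = None) -> Tensor:
    """Full generator pass on one window of frames.

    ``frames`` in [0, 1], shape (T, H, W, 3); output Tensor (T, 3, H, W) in
    [-1, 1].  The masked input X = Y * (1 - M) is computed here.
    """
    config = config or state.config
    y = np.asarray(frames, dtype=float) * 2.0 - 1.0
    m = np.asarray(masks, dtype=float)
    x = y * (1.0 - m[..., None])
    feats = encode_frames(x, m, state)
    fused = transformer_forward(feats, m, config, state)
    return _decode(fused, state)


def window_indices(T: int, targets, n: int, s: int) -> list:
    """Conditioning set for a group of target frames: neighbours plus
    distant frames sampled every s frames (0-based)."""
    idx = set()
    for t in targets:
        lo, hi = max(0, t - n), min(T - 1, t + n)
        idx.update(range(lo, hi + 1))
    idx.update(range(0, T, s))
    return sorted(idx)


def inpaint_clip(clip: np.ndarray, masks: np.ndarray, state: GeneratorState,
                 config: TransformerConfig | None = None, composite: bool = True,
                 temporal: bool = True) -> np.ndarray:
    """Inpaint a clip of arbitrary length with sliding target windows.

    Each group of 2n+1 consecutive target frames is generated conditioned on
    its neighbours and on distant frames at stride s.  With ``composite``
    (default) valid pixels are passed through untouched:
    Y_final = X * (1-M) + Yhat * M.  ``temporal=False`` forces single-frame
    windows (the no-temporal ablation).
    """
    config = config or state.config
    clip = np.asarray(clip, dtype=float)
    masks = np.asarray(masks, dtype=float)
    T = clip.shape[0]
    if T == 0:
        raise ValueError("empty clip")
    n = config.neighbor_window if temporal else 0
    s = config.distant_rate
    group = 2 * n + 1
    out = np.empty_like(clip)
    for g0 in range(0, T, group):
        targets = list(range(g0, min(g0 + group, T)))
        if temporal:
            window = window_indices(T, targets, n, s)
        else:
            window = targets
        yhat = generator_forward(clip[window], masks[window], state, config).data
        yhat = (yhat.transpose(0, 2, 3, 1) + 1.0) / 2.0
        for pos, t in enumerate(window):
            if t in targets:
                out[t] = yhat[pos]
    out = np.clip(out, 0.0, 1.0)
    if composite:
        m3 = masks[..., None]
        out = clip * (1.0 - m3) + out * m3
    return out


def discriminator_score(clip: np.ndarray | Tensor, dstate: DiscriminatorState) -> Tensor:
    """Spatio-temporal patch scores for a clip (T,H,W,3) in [0,1].

    Returns a Tensor of shape (T-2, h', w') of unbounded real scores.
    """
    p = dstate.params
    if isinstance(clip, Tensor):
        x = clip  # already (1,3,T,H,W), normalised
    else:
        c = np.asarray(clip, dtype=float) * 2.0 - 1.0
        x = Tensor(c.transpose(3, 0, 1, 2)[None])  # (1,3,T,H,W)
    if x.shape[2] < DiscriminatorState.RECEPTIVE_T:
        raise ValueError(
            f"clip shorter than discriminator receptive depth "
            f"({DiscriminatorState.RECEPTIVE_T} frames)"
        )
    t = conv3d(x, p["d1.w"], p["d1.b"], stride=(1, 2, 2), padding=(1, 2, 2)).relu()
    t = conv3d(t, p["d2.w"], p["d2.b"], stride=(1, 2, 2), padding=(1, 2, 2)).relu()
    t = conv3d(t, p["d3.w"], p["d3.b"], stride=(1, 2, 2), padding=(1, 2, 2)).relu()
    t = conv3d(t, p["d4.w"], p["d4.b"], stride=(1, 1, 1), padding=(0, 2, 2))
    tt, hh, ww = t.shape[2], t.shape[3], t.shape[4]
    return t.reshape(tt, hh, ww)


# -- checkpoint I/O -------------------------------------------------------


def save_checkpoint(path, state: GeneratorState, dstate: DiscriminatorState | None = None,
                    extra: dict | None = None) -> None:
    """Single-file checkpoint: npz arrays plus a JSON header."""
    header = {"config": state.config.to_dict(), "seed": state.seed}
    if extra:
        header.update(extra)
    arrays = {f"g::{k}": v.data for k, v in state.params.items()}
    if dstate is not None:
        arrays.update({f"d::{k}": v.data for k, v in dstate.params.items()})
        header["disc_base_channels"] = dstate.base_channels
        header["disc_seed"] = dstate.seed
    arrays["__header__"] = np.frombuffer(
        json.dumps(header).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Returns (GeneratorState, DiscriminatorState | None, header dict)."""
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode("utf-8"))
        config = TransformerConfig.from_dict(header["config"])
        state = GeneratorState(config, seed=header.get("seed", 0))
        for k in state.params:
            state.params[k].data = z[f"g::{k}"].copy()
        dstate = None
        if any(k.startswith("d::") for k in z.files):
            dstate = DiscriminatorState(
                base_channels=header.get("disc_base_channels", 16),
                seed=header.get("disc_seed", 0),
            )
            for k in dstate.params:
                dstate.params[k].data = z[f"d::{k}"].copy()
    return state, dstate, header
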