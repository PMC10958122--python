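"""Seeded synthetic endoscopy-like data: clips, masks, two-view scenes, stereo.

The clip generator emulates the aspects of gastrointestinal endoscopy that
matter for specularity inpainting without attempting photorealism: a
smoothly moving mucosa-like background (multi-octave value noise in a
reddish palette, crossed by darker Bezier "vein" curves) over which
saturated specular blobs with darkened surrounding rings move
*discontinuously* — jumping, unlike the tissue, from frame to frame.  The
returned mask marks the full corrupted footprint (saturated core plus dark
ring), so clean and corrupted frames agree exactly wherever the mask is 0.

Two-view scenes and stereo pairs carry exact ground truth (relative pose /
disparity) and serve as oracles for the geometry and disparity harnesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

__all__ = [
    "TextureParams",
    "MotionParams",
    "HighlightParams",
    "SyntheticSceneSpec",
    "TwoViewScene",
    "generate_clip",
    "generate_two_view_scene",
    "generate_stereo_pair",
    "cubic_bezier",
]


def cubic_bezier(control: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Evaluate a cubic Bezier curve with 4 control points at parameters ts."""
    p = np.asarray(control, dtype=float)
    if p.shape[0] != 4:
        raise ValueError("cubic Bezier needs 4 control points")
    t = np.asarray(ts, dtype=float)[:, None]
    return ((1 - t) ** 3 * p[0] + 3 * (1 - t) ** 2 * t * p[1]
            + 3 * (1 - t) * t**2 * p[2] + t**3 * p[3])


@dataclass
class TextureParams:
    octaves: int = 4
    vein_count: int = 6
    vein_width: float = 1.5
    color_dark: tuple = (0.45, 0.15, 0.12)
    color_light: tuple = (0.85, 0.45, 0.35)
    vein_color: tuple = (0.35, 0.05, 0.08)


@dataclass
class MotionParams:
    """Per-frame 2D similarity random walk of the viewing window."""

    translation_step: float = 0.8  # px per frame (std of walk step)
    rotation_step: float = 0.004   # radians per frame
    scale_step: float = 0.002


@dataclass
class HighlightParams:
    count: int = 4
    radius_range: tuple = (3, 7)
    saturation: float = 0.98
    ring_width: int = 2
    ring_darken: float = 0.55
    jump_prob: float = 0.3
    drift_px: float = 1.0
    centers: list | None = None  # optional fixed (row, col) per blob
    radii: list | None = None    # optional fixed radii per blob


@dataclass
class SyntheticSceneSpec:
    frame_count: int = 24
    frame_size: tuple = (64, 64)
    texture_params: TextureParams = field(default_factory=TextureParams)
    motion_model: MotionParams = field(default_factory=MotionParams)
    highlight_params: HighlightParams = field(default_factory=HighlightParams)
    seed: int = 0

    def __post_init__(self):
        h, w = self.frame_size
        if self.frame_count < 1:
            raise ValueError("frame_count must be >= 1")
        if h < 32 or w < 32:
            raise ValueError("frame size must be at least 32x32")
        if not 0.0 <= self.highlight_params.jump_prob <= 1.0:
            raise ValueError("jump probability must lie in [0, 1]")


def _value_noise(rng: np.random.Generator, shape: tuple, octaves: int) -> np.ndarray:
    h, w = shape
    acc = np.zeros(shape)
    norm = 0.0
    for k in range(octaves):
        step = 2 ** (octaves - k)
        gh, gw = max(2, h // step + 2), max(2, w // step + 2)
        grid = rng.random((gh, gw))
        up = ndimage.zoom(grid, (h / gh, w / gw), order=3, grid_mode=True,
                          mode="nearest")
        wgt = 0.5**k
        acc += wgt * up[:h, :w]
        norm += wgt
    acc /= norm
    lo, hi = acc.min(), acc.max()
    return (acc - lo) / (hi - lo + 1e-12)


def _render_canvas(rng: np.random.Generator, shape: tuple, tex: TextureParams) -> np.ndarray:
    h, w = shape
    noise = _value_noise(rng, shape, tex.octaves)
    c0 = np.asarray(tex.color_dark)
    c1 = np.asarray(tex.color_light)
    canvas = c0 + (c1 - c0) * noise[..., None]
    # vein curves: cubic Beziers stamped with a round brush
    yy, xx = np.mgrid[0:h, 0:w]
    vein_alpha = np.zeros(shape)
    for _ in range(tex.vein_count):
        ctrl = rng.random((4, 2)) * [h, w]
        pts = cubic_bezier(ctrl, np.linspace(0, 1, 4 * max(h, w)))
        a = np.zeros(shape, dtype=bool)
        r = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
        c = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
        a[r, c] = True
        dist = ndimage.distance_transform_edt(~a)
        vein_alpha = np.maximum(vein_alpha, np.clip(1.0 - dist / tex.vein_width, 0, 1))
    canvas = canvas * (1 - vein_alpha[..., None]) + np.asarray(tex.vein_color) * vein_alpha[..., None]
    canvas = ndimage.gaussian_filter(canvas, sigma=(0.6, 0.6, 0))
    return np.clip(canvas, 0.0, 1.0)


def _motion_transforms(rng, T: int, motion: MotionParams):
    """Cumulative similarity parameters (angle, scale, tx, ty) per frame."""
    ang = np.cumsum(rng.normal(0, motion.rotation_step, T))
    scl = np.exp(np.cumsum(rng.normal(0, motion.scale_step, T)))
    tx = np.cumsum(rng.normal(0, motion.translation_step, T))
    ty = np.cumsum(rng.normal(0, motion.translation_step, T))
    ang[0], scl[0], tx[0], ty[0] = 0.0, 1.0, 0.0, 0.0
    return ang, scl, tx, ty


def generate_clip(spec: SyntheticSceneSpec):
    """Render (clean, masks, corrupted) for a spec; bit-identical per seed.

    clean/corrupted: (T, H, W, 3) float in [0, 1]; masks: (T, H, W) uint8,
    1 = specular hole (saturated core plus dark ring).
    """
    T = spec.frame_count
    h, w = spec.frame_size
    pad = max(16, int(0.25 * max(h, w)))
    rng = np.random.default_rng(spec.seed)
    canvas = _render_canvas(rng, (h + 2 * pad, w + 2 * pad), spec.texture_params)

    ang, scl, tx, ty = _motion_transforms(rng, T, spec.motion_model)
    centre = np.array([(h + 2 * pad) / 2.0, (w + 2 * pad) / 2.0])
    clean = np.empty((T, h, w, 3))
    for t in range(T):
        # map output frame coords -> canvas coords (similarity about centre)
        tf = (
            sktransform.SimilarityTransform(translation=-centre[::-1])
            + sktransform.SimilarityTransform(rotation=ang[t], scale=scl[t])
            + sktransform.SimilarityTransform(translation=centre[::-1] + [tx[t], ty[t]])
        )
        warped = sktransform.warp(canvas, tf.inverse, order=1, mode="reflect")
        clean[t] = warped[pad : pad + h, pad : pad + w]

    hp = spec.highlight_params
    masks = np.zeros((T, h, w), dtype=np.uint8)
    corrupted = clean.copy()
    if hp.count > 0:
        if hp.radii is not None:
            radii = np.asarray(hp.radii, dtype=float)
        else:
            radii = rng.uniform(*hp.radius_range, size=hp.count)
        if hp.centers is not None:
            pos = np.asarray(hp.centers, dtype=float).copy()
        else:
            pos = np.column_stack(
                [rng.uniform(0, h, hp.count), rng.uniform(0, w, hp.count)]
            )
        yy, xx = np.mgrid[0:h, 0:w]
        for t in range(T):
            if t > 0:
                for b in range(hp.count):
                    if rng.random() < hp.jump_prob:
                        pos[b] = [rng.uniform(0, h), rng.uniform(0, w)]
                    else:
                        pos[b] += rng.normal(0, hp.drift_px, 2)
                        pos[b, 0] = np.clip(pos[b, 0], 0, h - 1)
                        pos[b, 1] = np.clip(pos[b, 1], 0, w - 1)
            frame = corrupted[t]
            for b in range(hp.count):
                r = radii[b]
                d = np.hypot(yy - pos[b, 0], xx - pos[b, 1])
                blob = d <= r + hp.ring_width
                if not blob.any():
                    continue
                masks[t][blob] = 1
                core_alpha = np.clip(np.exp(-(d**2) / (2 * (r / 1.5) ** 2)) * 1.6, 0, 1)
                core = d <= r
                ring = blob & ~core
                white = np.array([1.0, 1.0, 1.0]) * hp.saturation
                frame[core] = (
                    frame[core] * (1 - core_alpha[core, None])
                    + white * core_alpha[core, None]
                )
                frame[d <= 0.7 * r] = white
                frame[ring] *= hp.ring_darken
    return clean, masks, np.clip(corrupted, 0.0, 1.0)


@dataclass
class TwoViewScene:
    points_3d: np.ndarray      # (N, 3) in the first camera frame
    intrinsics: np.ndarray     # (3, 3)
    rotation_gt: np.ndarray    # (3, 3), x_cam2 = R x_cam1 + t
    translation_gt: np.ndarray # (3,)
    proj_a: np.ndarray         # (N, 2) pixel (row, col) coordinates, view 1
    proj_b: np.ndarray         # (N, 2) pixel (row, col) coordinates, view 2


def _rot_y(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def generate_two_view_scene(n_points: int, rotation_deg: float, translation,
                            noise_px: float = 0.0, seed: int = 0,
                            image_size=(480, 640), focal: float = 500.0) -> TwoViewScene:
    """Random 3D points viewed by two calibrated cameras with known motion.

    The second camera is related to the first by a rotation about the y axis
    of ``rotation_deg`` degrees and translation ``translation`` (camera
    convention x2 = R x1 + t).  With ``noise_px = 0`` the projections obey the
    pinhole model exactly.
    """
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    t_vec = np.asarray(translation, dtype=float)
    if np.linalg.norm(t_vec) == 0:
        raise ValueError("translation must be non-zero "
                         "(essential-matrix direction undefined)")
    rng = np.random.default_rng(seed)
    hgt, wid = image_size
    K = np.array([[focal, 0, wid / 2.0], [0, focal, hgt / 2.0], [0, 0, 1.0]])
    R = _rot_y(rotation_deg)

    pts, pa, pb = [], [], []
    attempts = 0
    while len(pts) < n_points:
        attempts += 1
        if attempts > 200:
            raise RuntimeError("could not place enough points in both views")
        cand = np.column_stack(
            [rng.uniform(-2, 2, 4 * n_points), rng.uniform(-1.5, 1.5, 4 * n_points),
             rng.uniform(4, 9, 4 * n_points)]
        )
        x2 = cand @ R.T + t_vec
        ok = (cand[:, 2] > 0.1) & (x2[:, 2] > 0.1)
        u1 = (cand @ K.T)
        u1 = u1[:, :2] / u1[:, 2:3]
        u2 = (x2 @ K.T)
        u2 = u2[:, :2] / u2[:, 2:3]
        ok &= (u1[:, 0] >= 0) & (u1[:, 0] < wid) & (u1[:, 1] >= 0) & (u1[:, 1] < hgt)
        ok &= (u2[:, 0] >= 0) & (u2[:, 0] < wid) & (u2[:, 1] >= 0) & (u2[:, 1] < hgt)
        for i in np.flatnonzero(ok):
            if len(pts) >= n_points:
                break
            pts.append(cand[i])
            pa.append(u1[i][::-1])  # store (row, col) per package convention
            pb.append(u2[i][::-1])
    pa = np.asarray(pa)
    pb = np.asarray(pb)
    if noise_px > 0:
        pa = pa + rng.normal(0, noise_px, pa.shape)
        pb = pb + rng.normal(0, noise_px, pb.shape)
    return TwoViewScene(np.asarray(pts), K, R, t_vec, pa, pb)


def generate_stereo_pair(spec: SyntheticSceneSpec, disparity_fn):
    """Rectified stereo pair with exact ground-truth disparity.

    ``disparity_fn(rows, cols) -> d >= 0`` is evaluated on the pixel grid of
    the right image; the right image samples the left at column c + d(r, c).
    Returns (left, right, disparity_gt) with the disparity registered to the
    right image.
    """
    h, w = spec.frame_size
    rng = np.random.default_rng(spec.seed)
    left = _render_canvas(rng, (h, w), spec.texture_params)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    disp = np.asarray(disparity_fn(yy, xx), dtype=float)
    if disp.shape != (h, w):
        disp = np.broadcast_to(disp, (h, w)).astype(float)
    if (disp < 0).any():
        raise ValueError("disparity must be non-negative")
    right = np.empty_like(left)
    for ch in range(3):
        right[..., ch] = ndimage.map_coordinates(
            left[..., ch], [yy, xx + disp], order=1, mode="nearest"
        )
    return left, right, disp
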