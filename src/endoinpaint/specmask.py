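"""Specular-highlight detection and pseudo-ground-truth mask construction.

Detection follows the dichromatic-reflection-model family of rules: a
specular pixel is either absolutely bright and unsaturated in colour
(interface reflection swamps body colour), or relatively much brighter
than its local neighbourhood in some channel.  Detected masks are
post-processed by morphological dilation (diamond at the raw stage;
ellipse to cover the dark rings that border highlights) and then turned
into *pseudo ground truth*: the mask is translated by a fixed per-sequence
offset onto unoccluded tissue, and any overlap with the (guard-dilated)
original specularity is removed, so the texture behind the translated mask
is known.  Two variants exist — the training mask dilates before
translating, the evaluation mask translates first, removes the overlap
with the ball-dilated original, then dilates.

Coordinates are (row, col), 0-based, top-left origin; a translation
(dx, dy) shifts by dx columns and dy rows.  Mask polarity: 1 = hole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .synthdata import cubic_bezier

__all__ = [
    "DetectionParams",
    "PseudoGTSpec",
    "detect_specular_mask",
    "dilate_mask",
    "structuring_element",
    "translate_mask",
    "make_pseudo_mask",
    "make_pseudo_mask_sequence",
    "generate_bezier_random_masks",
]


@dataclass
class DetectionParams:
    absolute_intensity_thresh: float = 0.85
    absolute_saturation_thresh: float = 0.25
    relative_ratio_thresh: float = 1.5
    local_window: int = 15
    min_region_area: int = 5

    def __post_init__(self):
        if not (0 <= self.absolute_intensity_thresh <= 1):
            raise ValueError("absolute_intensity_thresh must be in [0,1]")
        if not (0 <= self.absolute_saturation_thresh <= 1):
            raise ValueError("absolute_saturation_thresh must be in [0,1]")
        if self.relative_ratio_thresh <= 1:
            raise ValueError("relative_ratio_thresh must exceed 1")
        if self.local_window < 3 or self.local_window % 2 == 0:
            raise ValueError("local_window must be an odd integer >= 3")


@dataclass
class PseudoGTSpec:
    translation: tuple = None  # (dx, dy) pixels; default +0.2*W, 0
    guard_radius: int = 3
    ellipse_radii: tuple = (5, 3)
    diamond_radius: int = 1
    variant: str = "training"

    def __post_init__(self):
        if self.variant not in ("training", "evaluation"):
            raise ValueError("variant must be 'training' or 'evaluation'")
        if self.guard_radius < 0 or self.diamond_radius < 0 or min(self.ellipse_radii) < 0:
            raise ValueError("radii must be >= 0")
        if self.translation is not None and tuple(self.translation) == (0, 0):
            raise ValueError("translation must be non-zero")


def detect_specular_mask(frame: np.ndarray, params: DetectionParams | None = None) -> np.ndarray:
    """Binary specularity mask for one RGB frame with values in [0, 1].

    Union of (i) the absolute rule — intensity above threshold and colour
    saturation below threshold — and (ii) the relative rule — any channel
    exceeding ratio x its local median.  Components below
    ``min_region_area`` pixels are discarded.
    """
    params = params or DetectionParams()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("expected an RGB frame (H, W, 3)")
    intensity = frame.mean(axis=2)
    mx = frame.max(axis=2)
    mn = frame.min(axis=2)
    saturation = np.where(mx > 0, (mx - mn) / (mx + 1e-12), 0.0)
    absolute = (intensity > params.absolute_intensity_thresh) & (
        saturation < params.absolute_saturation_thresh
    )
    relative = np.zeros_like(absolute)
    for ch in range(3):
        med = ndimage.median_filter(frame[..., ch], size=params.local_window,
                                    mode="reflect")
        relative |= frame[..., ch] > params.relative_ratio_thresh * med
    mask = absolute | relative
    if params.min_region_area > 1:
        # drop components with fewer than min_region_area pixels
        mask = morphology.remove_small_objects(mask, max_size=params.min_region_area - 1)
    return mask.astype(np.uint8)


def structuring_element(element: str, radius_spec) -> np.ndarray:
    """Footprints for dilation: 'diamond' r, 'ball' r (disk), 'ellipse' (a, b)."""
    if element == "diamond":
        r = int(radius_spec)
        if r < 0:
            raise ValueError("radius must be >= 0")
        return morphology.diamond(r) if r > 0 else np.ones((1, 1), dtype=np.uint8)
    if element == "ball":
        r = int(radius_spec)
        if r < 0:
            raise ValueError("radius must be >= 0")
        return morphology.disk(r) if r > 0 else np.ones((1, 1), dtype=np.uint8)
    if element == "ellipse":
        a, b = radius_spec
        if a < 0 or b < 0:
            raise ValueError("radii must be >= 0")
        if a == 0 and b == 0:
            return np.ones((1, 1), dtype=np.uint8)
        # ellipse with horizontal semi-axis a, vertical semi-axis b
        yy, xx = np.mgrid[-b : b + 1, -a : a + 1]
        return ((xx / max(a, 1e-9)) ** 2 + (yy / max(b, 1e-9)) ** 2 <= 1.0).astype(np.uint8)
    raise ValueError(f"unknown structuring element {element!r}")


def dilate_mask(mask: np.ndarray, element: str, radius_spec) -> np.ndarray:
    """Morphological dilation of a binary mask with a named element."""
    mask = np.asarray(mask)
    se = structuring_element(element, radius_spec)
    return ndimage.binary_dilation(mask > 0, structure=se.astype(bool)).astype(np.uint8)


def translate_mask(mask: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Shift a mask by dx columns / dy rows; content leaving the frame is cropped."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    src_r = slice(max(0, -dy), min(h, h - dy))
    src_c = slice(max(0, -dx), min(w, w - dx))
    dst_r = slice(max(0, dy), min(h, h + dy))
    dst_c = slice(max(0, dx), min(w, w + dx))
    out[dst_r, dst_c] = mask[src_r, src_c]
    return out


def default_translation(frame_width: int) -> tuple:
    """Rightward shift of 20% of the frame width."""
    return (max(1, int(round(0.2 * frame_width))), 0)


def make_pseudo_mask(seg_mask: np.ndarray, spec: PseudoGTSpec) -> np.ndarray:
    """Pseudo-ground-truth mask from a raw detection mask.

    training variant:  dilate(ellipse) -> translate -> remove overlap with the
    guard-dilated original.  evaluation variant: translate -> remove overlap
    with the ball-dilated original -> dilate(ellipse).  In both variants the
    result is disjoint from the guard-dilated original mask, so it covers
    only originally-valid texture.
    """
    seg_mask = (np.asarray(seg_mask) > 0).astype(np.uint8)
    if spec.translation is None:
        dx, dy = default_translation(seg_mask.shape[1])
    else:
        dx, dy = spec.translation
    if (dx, dy) == (0, 0):
        raise ValueError("translation must be non-zero")
    guard = dilate_mask(seg_mask, "ball", spec.guard_radius)
    if spec.variant == "training":
        m = dilate_mask(seg_mask, "ellipse", spec.ellipse_radii)
        m = translate_mask(m, dx, dy)
    else:
        m = translate_mask(seg_mask, dx, dy)
        m = (m & ~guard).astype(np.uint8)
        m = dilate_mask(m, "ellipse", spec.ellipse_radii)
    m = (m & ~guard).astype(np.uint8)
    return m


def make_pseudo_mask_sequence(seg_masks: np.ndarray, spec: PseudoGTSpec):
    """Apply :func:`make_pseudo_mask` with a single fixed translation to every
    frame of a sequence.  Returns (pseudo_masks, (dx, dy))."""
    seg_masks = np.asarray(seg_masks)
    if spec.translation is None:
        dx, dy = default_translation(seg_masks.shape[2])
        spec = PseudoGTSpec(
            translation=(dx, dy), guard_radius=spec.guard_radius,
            ellipse_radii=spec.ellipse_radii, diamond_radius=spec.diamond_radius,
            variant=spec.variant,
        )
    out = np.stack([make_pseudo_mask(m, spec) for m in seg_masks])
    return out, tuple(spec.translation)


def generate_bezier_random_masks(T: int, frame_size: tuple, seed: int = 0,
                                 shape_radius: tuple = (8, 16), n_knots: int = 7,
                                 max_speed: float | None = None) -> np.ndarray:
    """Temporally smooth random masks for the initialisation training phase.

    One random blob shape is drawn per sequence; its centroid moves along a
    cubic Bezier trajectory sampled at T points, giving the smooth,
    continuous motion used to pre-train the inpainter before fine-tuning on
    specularity-derived masks.  The control polygon is shrunk if necessary so
    the per-frame centroid step never exceeds ``max_speed`` pixels (default
    0.45x the blob radius, which keeps consecutive-frame overlap high).
    Returns (T, H, W) uint8 masks.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    h, w = frame_size
    if h < 8 or w < 8:
        raise ValueError("frame too small")
    rng = np.random.default_rng(seed)
    # random star-convex polygon blob
    base_r = rng.uniform(*shape_radius)
    angles = np.linspace(0, 2 * np.pi, n_knots, endpoint=False)
    radii = base_r * rng.uniform(0.6, 1.4, n_knots)
    size = int(2 * np.ceil(radii.max()) + 3)
    cy = cx = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    theta = np.arctan2(yy - cy, xx - cx)
    rad = np.hypot(yy - cy, xx - cx)
    bound = np.interp(theta, np.sort(angles) - np.pi,
                      radii[np.argsort(angles)], period=2 * np.pi)
    shape = (rad <= bound).astype(np.uint8)

    margin = size // 2 + 1
    if 2 * margin >= min(h, w):
        raise ValueError(
            f"blob of radius up to {radii.max():.1f}px cannot move inside a "
            f"{h}x{w} frame; reduce shape_radius"
        )
    ctrl = np.column_stack(
        [rng.uniform(margin, h - margin, 4), rng.uniform(margin, w - margin, 4)]
    )
    if max_speed is None:
        max_speed = 0.45 * base_r
    if T > 1:
        # |B'(t)| <= 3 max|P_{i+1}-P_i|, so per-frame step <= 3 max|dP|/(T-1)
        step_bound = 3.0 * np.linalg.norm(np.diff(ctrl, axis=0), axis=1).max() / (T - 1)
        if step_bound > max_speed:
            centre_pt = ctrl.mean(axis=0)
            ctrl = centre_pt + (ctrl - centre_pt) * (max_speed / step_bound)
    ts = np.zeros(1) if T == 1 else np.linspace(0, 1, T)
    centres = cubic_bezier(ctrl, ts)
    masks = np.zeros((T, h, w), dtype=np.uint8)
    for t in range(T):
        r0 = int(round(centres[t, 0])) - cy
        c0 = int(round(centres[t, 1])) - cx
        rs, cs = slice(max(0, r0), min(h, r0 + size)), slice(max(0, c0), min(w, c0 + size))
        srs = slice(rs.start - r0, rs.stop - r0)
        scs = slice(cs.start - c0, cs.stop - c0)
        masks[t, rs, cs] = shape[srs, scs]
    return masks
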