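"""Sparse matching, relative-pose estimation and pose-error statistics.

This harness quantifies how inpainting changes image correspondence: ORB
keypoints matched brute-force with Lowe's ratio test (or dense-flow
correspondences subsampled on a grid) feed a calibrated relative-pose
estimator — a normalized eight-point essential-matrix solver inside
RANSAC with Sampson-distance scoring, followed by decomposition and a
chirality check that keeps the (R, t) hypothesis placing the most points
in front of both cameras.  Errors against ground truth are the rotation
geodesic angle (RRE) and the angle between translation directions (RTE),
both in degrees; the +-t sign ambiguity of the essential matrix is folded
so anti-parallel directions score 0.  Frame pairs are drawn with a moving
20-frame window along the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import ORB, match_descriptors

__all__ = [
    "MatchSet",
    "PoseErrors",
    "RansacParams",
    "match_features",
    "flow_to_matches",
    "estimate_relative_pose",
    "rotation_error",
    "translation_error",
    "window_pairs",
    "summarize_pose_errors",
]


@dataclass
class MatchSet:
    keypoints_a: np.ndarray      # (Na, 2) (row, col)
    keypoints_b: np.ndarray      # (Nb, 2)
    matches: np.ndarray          # (M, 2) index pairs into keypoints_a/b
    ratio_threshold: float
    empty_flag: bool = False

    @property
    def points_a(self) -> np.ndarray:
        return self.keypoints_a[self.matches[:, 0]] if len(self.matches) else np.empty((0, 2))

    @property
    def points_b(self) -> np.ndarray:
        return self.keypoints_b[self.matches[:, 1]] if len(self.matches) else np.empty((0, 2))

    def __len__(self) -> int:
        return len(self.matches)


@dataclass
class PoseErrors:
    rte_deg: float
    rre_deg: float
    inliers: int
    pair: tuple = (0, 0)
    degenerate: bool = False


@dataclass
class RansacParams:
    threshold_px: float = 1.0
    confidence: float = 0.999
    max_iterations: int = 2000
    seed: int = 0
    min_parallax_px: float = 0.5  # below this median rotation-compensated
    #                               displacement the translation is unobservable


def match_features(frame_a: np.ndarray, frame_b: np.ndarray,
                   n_keypoints: int = 2000, ratio: float = 0.75) -> MatchSet:
    """ORB keypoints + brute-force matching with Lowe's ratio test."""
    def prep(f):
        f = np.asarray(f, dtype=float)
        if f.ndim == 3:
            f = rgb2gray(f)
        return f

    ga, gb = prep(frame_a), prep(frame_b)
    kps, descs = [], []
    for g in (ga, gb):
        orb = ORB(n_keypoints=n_keypoints)
        try:
            orb.detect_and_extract(g)
            kps.append(orb.keypoints)
            descs.append(orb.descriptors)
        except RuntimeError:  # no keypoints found (e.g. blank frame)
            kps.append(np.empty((0, 2)))
            descs.append(np.empty((0, 256), dtype=bool))
    if len(kps[0]) < 2 or len(kps[1]) < 2:
        return MatchSet(kps[0], kps[1], np.empty((0, 2), dtype=int), ratio, True)
    matches = match_descriptors(descs[0], descs[1], cross_check=False,
                                max_ratio=ratio)
    return MatchSet(kps[0], kps[1], matches, ratio, len(matches) == 0)


def flow_to_matches(flow_field: np.ndarray, stride: int = 8,
                    validity_mask: np.ndarray | None = None) -> MatchSet:
    """Dense flow -> correspondences (p, p + flow(p)) on a stride grid.

    ``flow_field`` is (H, W, 2) with (d_row, d_col) displacements.
    """
    flow = np.asarray(flow_field, dtype=float)
    h, w = flow.shape[:2]
    if stride >= min(h, w):
        raise ValueError("stride must be smaller than the frame")
    rr, cc = np.mgrid[0:h:stride, 0:w:stride]
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    disp = flow[rr.ravel(), cc.ravel()]
    tgt = pts + disp
    keep = (tgt[:, 0] >= 0) & (tgt[:, 0] < h) & (tgt[:, 1] >= 0) & (tgt[:, 1] < w)
    if validity_mask is not None:
        vm = np.asarray(validity_mask) > 0
        keep &= vm[rr.ravel(), cc.ravel()]
    pa, pb = pts[keep], tgt[keep]
    matches = np.column_stack([np.arange(len(pa))] * 2)
    return MatchSet(pa, pb, matches, 1.0, len(pa) == 0)


# -- essential-matrix machinery -------------------------------------------


def _normalized(pts_px: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Pixel (row, col) -> normalised homogeneous camera coordinates."""
    uv = np.column_stack([pts_px[:, 1], pts_px[:, 0], np.ones(len(pts_px))])
    return (np.linalg.inv(K) @ uv.T).T


def _eight_point(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Essential matrix from >= 8 normalised correspondences (x2' E x1 = 0)."""
    a = np.column_stack([
        x2[:, 0] * x1[:, 0], x2[:, 0] * x1[:, 1], x2[:, 0],
        x2[:, 1] * x1[:, 0], x2[:, 1] * x1[:, 1], x2[:, 1],
        x1[:, 0], x1[:, 1], np.ones(len(x1)),
    ])
    _, _, vt = np.linalg.svd(a)
    E = vt[-1].reshape(3, 3)
    u, s, vt = np.linalg.svd(E)
    sv = (s[0] + s[1]) / 2.0
    return u @ np.diag([sv, sv, 0.0]) @ vt


def _sampson_sq(E: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    ex1 = x1 @ E.T          # E x1
    etx2 = x2 @ E           # E^T x2
    num = np.einsum("ij,ij->i", x2, ex1) ** 2
    den = ex1[:, 0] ** 2 + ex1[:, 1] ** 2 + etx2[:, 0] ** 2 + etx2[:, 1] ** 2
    return num / np.maximum(den, 1e-300)


def _triangulate_depths(R, t, x1, x2):
    """Depths in both cameras for midpoint triangulation of normalised rays."""
    z1 = np.empty(len(x1))
    z2 = np.empty(len(x1))
    for i, (a, b) in enumerate(zip(x1, x2)):
        # solve [a, -R^T b] [z1, z2]^T ~= -R^T t  (x1 = z1*a ; x2 = z2*b)
        A = np.column_stack([a, -(R.T @ b)])
        rhs = -(R.T @ t)
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        z1[i], z2[i] = sol[0], sol[1]
    return z1, z2


def _decompose(E: np.ndarray):
    u, _, vt = np.linalg.svd(E)
    if np.linalg.det(u) < 0:
        u = -u
    if np.linalg.det(vt) < 0:
        vt = -vt
    W = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]])
    R1, R2 = u @ W @ vt, u @ W.T @ vt
    t = u[:, 2]
    return [(R1, t), (R1, -t), (R2, t), (R2, -t)]


def estimate_relative_pose(matches: MatchSet, intrinsics: np.ndarray,
                           params: RansacParams | None = None):
    """(R, t_unit, inlier_count, degenerate_flag) from pixel correspondences.

    RANSAC over eight-point essential-matrix hypotheses scored by Sampson
    distance; the winning hypothesis is refit on its inliers and decomposed,
    keeping the chirality-consistent (R, t).  Near-zero translation
    (no parallax after rotation compensation) sets the degenerate flag.
    """
    params = params or RansacParams()
    if len(matches) < 5:
        raise ValueError("at least 5 matches required for pose estimation")
    K = np.asarray(intrinsics, dtype=float)
    x1 = _normalized(matches.points_a, K)
    x2 = _normalized(matches.points_b, K)
    n = len(x1)
    f = (K[0, 0] + K[1, 1]) / 2.0
    thr = (params.threshold_px / f) ** 2
    rng = np.random.default_rng(params.seed)

    best_inl = None
    best_count = -1
    n_iter = params.max_iterations
    it = 0
    while it < n_iter:
        it += 1
        sample = rng.choice(n, size=min(8, n), replace=False)
        try:
            E = _eight_point(x1[sample], x2[sample])
        except np.linalg.LinAlgError:
            continue
        inl = _sampson_sq(E, x1, x2) < thr
        cnt = int(inl.sum())
        if cnt > best_count:
            best_count, best_inl = cnt, inl
            ratio = max(cnt / n, 1e-12)
            denom = np.log(max(1e-12, 1 - ratio**8))
            if denom < 0:
                n_iter = min(params.max_iterations,
                             int(np.ceil(np.log(1 - params.confidence) / denom)))
    if best_inl is None or best_count < 8:
        raise RuntimeError("RANSAC failed to find a valid essential matrix")
    E = _eight_point(x1[best_inl], x2[best_inl])
    inl = _sampson_sq(E, x1, x2) < thr
    xi1, xi2 = x1[inl], x2[inl]

    best_pose, best_front = None, -1
    for R, t in _decompose(E):
        z1, z2 = _triangulate_depths(R, t, xi1, xi2)
        front = int(((z1 > 0) & (z2 > 0)).sum())
        if front > best_front:
            best_front, best_pose = front, (R, t)
    R, t = best_pose
    t = t / np.linalg.norm(t)

    # degeneracy: rotation-compensated pixel displacement ~ parallax
    warped = xi1 @ R.T
    w_px = warped[:, :2] / warped[:, 2:3] * f
    b_px = xi2[:, :2] / xi2[:, 2:3] * f
    parallax = np.median(np.linalg.norm(w_px - b_px, axis=1))
    degenerate = parallax < params.min_parallax_px
    return R, t, int(inl.sum()), bool(degenerate)


def rotation_error(R_est: np.ndarray, R_gt: np.ndarray) -> float:
    """Geodesic angle (degrees) of R_est R_gt^T."""
    for R in (R_est, R_gt):
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-6:
            raise ValueError("input is not orthonormal")
    c = (np.trace(np.asarray(R_est) @ np.asarray(R_gt).T) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def translation_error(t_est: np.ndarray, t_gt: np.ndarray) -> float:
    """Angle (degrees) between translation directions, sign ambiguity folded."""
    a = np.asarray(t_est, dtype=float)
    b = np.asarray(t_gt, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm translation")
    c = np.clip(abs(a @ b) / (na * nb), 0.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def window_pairs(n_frames: int, window: int = 20):
    """Moving-window frame pairs (i, i + window); ([], flagged) when too short."""
    if n_frames <= window:
        return [], True
    return [(i, i + window) for i in range(n_frames - window)], False


def _quantile(x, q):
    return float(np.percentile(x, q, method="linear"))


def summarize_pose_errors(errors_orig, errors_inp) -> dict:
    """Summary statistics of the paired differences (original - inpainted).

    Pairs are matched by frame-pair indices.  For each metric (RTE, RRE,
    inliers): min/max/mean/25th/median/75th/IQR of the per-pair differences
    in native units, plus the mean of the per-pair signed relative
    differences in percent (``mean_delta_pct``, undefined pairs with a zero
    original value are dropped from that mean only).
    """
    key_o = {e.pair: e for e in errors_orig}
    key_i = {e.pair: e for e in errors_inp}
    if set(key_o) != set(key_i):
        raise ValueError("mismatched frame-pair sets")
    pairs = sorted(key_o)
    out = {}
    for metric, get in (
        ("RTE", lambda e: e.rte_deg),
        ("RRE", lambda e: e.rre_deg),
        ("inliers", lambda e: float(e.inliers)),
    ):
        delta = np.array([get(key_o[p]) - get(key_i[p]) for p in pairs])
        orig = np.array([get(key_o[p]) for p in pairs])
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(orig != 0, 100.0 * delta / orig, np.nan)
        q25, q75 = _quantile(delta, 25), _quantile(delta, 75)
        out[metric] = {
            "min": float(delta.min()),
            "max": float(delta.max()),
            "mean": float(delta.mean()),
            "p25": q25,
            "median": _quantile(delta, 50),
            "p75": q75,
            "iqr": q75 - q25,
            "mean_delta_pct": float(np.nanmean(rel)) if np.isfinite(rel).any() else float("nan"),
            "n_pairs": len(pairs),
        }
    return out
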