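"""Classic non-learning inpainting baselines.

``diffusion_inpaint`` fills holes with the harmonic (Laplace) interpolant
of the boundary values — the canonical diffusion baseline, maximally
smooth and subject to the maximum principle.  ``temporal_patch_inpaint``
is a greedy exemplar-based filler: hole patches are completed
boundary-first by copying the best-matching fully-valid patch found in a
spatio-temporal search window, scoring candidates by masked SSD on the
known overlap.  Both baselines are bit-exact identity outside the mask.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

__all__ = ["diffusion_inpaint", "temporal_patch_inpaint"]


def diffusion_inpaint(frame: np.ndarray, mask: np.ndarray, max_iter: int = 2000,
                      tol: float = 1e-6) -> np.ndarray:
    """Replace hole pixels by the harmonic interpolant of the boundary.

    Solves the Laplace equation over the hole with Dirichlet data from the
    valid pixels (sparse direct solve for small holes, conjugate gradients
    with the given tolerance/iteration budget otherwise).  Valid pixels are
    returned untouched.
    """
    frame = np.asarray(frame, dtype=float)
    single = frame.ndim == 2
    img = frame[..., None] if single else frame
    mask = np.asarray(mask) > 0
    if mask.shape != img.shape[:2]:
        raise ValueError("mask/frame shape mismatch")
    if mask.all():
        raise ValueError("mask covers the entire frame: no boundary to diffuse from")
    if not mask.any():
        return frame.copy()

    h, w = mask.shape
    idx = -np.ones((h, w), dtype=int)
    hole_rc = np.argwhere(mask)
    idx[mask] = np.arange(len(hole_rc))
    n = len(hole_rc)
    A = sparse.lil_matrix((n, n))
    rhs = np.zeros((n, img.shape[2]))
    for k, (r, c) in enumerate(hole_rc):
        neigh = 0
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w):
                continue
            neigh += 1
            if mask[rr, cc]:
                A[k, idx[rr, cc]] = -1.0
            else:
                rhs[k] += img[rr, cc]
        A[k, k] = neigh
    A = A.tocsr()
    out = img.copy()
    if n <= 20000:
        sol = spsolve(A, rhs)
        sol = np.atleast_2d(sol.reshape(n, -1))
    else:
        sol = np.empty_like(rhs)
        for ch in range(rhs.shape[1]):
            x, _ = sparse.linalg.cg(A, rhs[:, ch], rtol=tol, maxiter=max_iter)
            sol[:, ch] = x
    out[mask] = sol
    return out[..., 0] if single else out


def temporal_patch_inpaint(clip: np.ndarray, masks: np.ndarray, patch: tuple = (5, 5),
                           temporal_radius: int = 2, spatial_radius: int = 8,
                           passes: int = 4, source_log: list | None = None) -> np.ndarray:
    """Greedy onion-peel exemplar filling across space and time.

    Hole pixels are processed boundary-first; for each, the patch centred on
    it is compared (masked SSD over currently-known pixels, normalised by
    overlap size) against every fully-valid patch within ``spatial_radius``
    pixels and ``temporal_radius`` frames, and the unknown pixels are copied
    from the best match.  Ties break towards the smallest temporal offset,
    then raster order.  If a pass fills nothing, the spatial window is
    widened; if that fails too, an error is raised.
    """
    clip = np.asarray(clip, dtype=float).copy()
    known = ~(np.asarray(masks) > 0)
    T, h, w = known.shape
    pr, pc = patch
    if pr >= h or pc >= w:
        raise ValueError("patch must be smaller than the frame")
    rr, rc = pr // 2, pc // 2
    orig_known = known.copy()

    def fill_pass(radius: int) -> int:
        filled = 0
        for t in range(T):
            hole = ~known[t]
            if not hole.any():
                continue
            boundary = hole & ndimage.binary_dilation(known[t])
            targets = np.argwhere(boundary if boundary.any() else hole)
            for r, c in targets:
                if known[t, r, c]:
                    continue
                r0, c0 = r - rr, c - rc
                rs = slice(max(0, r0), min(h, r0 + pr))
                cs = slice(max(0, c0), min(w, c0 + pc))
                tgt = clip[t, rs, cs]
                tknown = known[t, rs, cs]
                if not tknown.any():
                    continue
                best = None
                for dt in sorted(range(-temporal_radius, temporal_radius + 1), key=abs):
                    ts = t + dt
                    if not 0 <= ts < T:
                        continue
                    for sr in range(max(rr, r - radius), min(h - (pr - rr), r + radius + 1)):
                        for sc in range(max(rc, c - radius), min(w - (pc - rc), c + radius + 1)):
                            srs = slice(sr - rr, sr - rr + tgt.shape[0])
                            scs = slice(sc - rc, sc - rc + tgt.shape[1])
                            cand_known = orig_known[ts, srs, scs]
                            if not cand_known.all():
                                continue
                            cand = clip[ts, srs, scs]
                            d = cand - tgt
                            ssd = float((d[tknown] ** 2).sum()) / tknown.sum()
                            if best is None or ssd < best[0] - 1e-15:
                                best = (ssd, ts, srs, scs)
                if best is None:
                    continue
                _, ts, srs, scs = best
                if source_log is not None:
                    source_log.append({
                        "target": (t, r, c),
                        "source": (ts, srs.start + (r - rs.start),
                                   scs.start + (c - cs.start)),
                    })
                unknown = ~known[t, rs, cs]
                clip[t, rs, cs][unknown] = clip[ts, srs, scs][unknown]
                known[t, rs, cs] |= unknown
                filled += int(unknown.sum())
        return filled

    radius = spatial_radius
    for _ in range(passes):
        if known.all():
            break
        if fill_pass(radius) == 0:
            radius = max(h, w)  # widen-window fallback
            if fill_pass(radius) == 0:
                raise RuntimeError("no valid candidate patch found for remaining holes")
    if not known.all():
        # keep peeling until done (onion-peel needs ~hole-radius passes)
        for _ in range(max(h, w)):
            if known.all():
                break
            if fill_pass(radius) == 0:
                raise RuntimeError("no valid candidate patch found for remaining holes")
    return clip
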