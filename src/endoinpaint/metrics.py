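"""Masked image-quality metrics, two-level report averaging, disparity errors.

PSNR/SSIM/MSE are computed over the hole region only (the pseudo mask),
since that is where inpainting acts: MSE and PSNR directly on the masked
pixels, SSIM as the mean over the region of interest of the full-frame
SSIM map (an 11-pixel Gaussian window, sigma 1.5).  Reports average per
frame within each video and then, unweighted, across videos.  Disparity
errors (RMS, EPE, Bad3%) are evaluated over the specularity region of the
disparity map, optionally including or excluding stereo-occluded pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "PSNR_CAP_DB",
    "MetricReport",
    "DisparityEval",
    "masked_mse",
    "masked_psnr",
    "masked_ssim",
    "frame_metrics",
    "aggregate_report",
    "disparity_errors",
    "percent_delta",
]

PSNR_CAP_DB = 100.0
FRAME_CAP_DEFAULT = 927  # evaluation-time cap on frames per video


def _check_roi(roi: np.ndarray, shape) -> np.ndarray:
    roi = np.asarray(roi) > 0
    if roi.shape != tuple(shape):
        raise ValueError("roi/frame shape mismatch")
    if not roi.any():
        raise ValueError("empty roi")
    return roi


def masked_mse(ref: np.ndarray, test: np.ndarray, roi: np.ndarray) -> float:
    """Mean squared difference over roi pixels, averaged over channels."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    roi = _check_roi(roi, ref.shape[:2])
    d2 = (ref - test) ** 2
    if d2.ndim == 3:
        d2 = d2.mean(axis=2)
    return float(d2[roi].mean())


def masked_psnr(ref: np.ndarray, test: np.ndarray, roi: np.ndarray,
                peak: float = 255.0):
    """PSNR (dB) over the roi; (value, capped_flag), capped at 100 dB."""
    mse = masked_mse(ref, test, roi)
    if mse == 0:
        return PSNR_CAP_DB, True
    val = 10.0 * np.log10(peak**2 / mse)
    if val >= PSNR_CAP_DB:
        return PSNR_CAP_DB, True
    return float(val), False


def masked_ssim(ref: np.ndarray, test: np.ndarray, roi: np.ndarray,
                data_range: float = 255.0) -> float:
    """Mean of the full-frame SSIM map over the roi (Gaussian window 11, sigma 1.5)."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    roi = _check_roi(roi, ref.shape[:2])
    if min(ref.shape[:2]) < 11:
        raise ValueError("frame smaller than the SSIM window")
    kwargs = dict(gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
                  data_range=data_range, full=True)
    if ref.ndim == 3:
        kwargs["channel_axis"] = 2
    _, smap = structural_similarity(ref, test, **kwargs)
    if smap.ndim == 3:
        smap = smap.mean(axis=2)
    return float(smap[roi].mean())


def frame_metrics(ref: np.ndarray, test: np.ndarray, roi: np.ndarray,
                  peak: float = 255.0) -> dict:
    psnr, capped = masked_psnr(ref, test, roi, peak)
    return {
        "mse": masked_mse(ref, test, roi),
        "psnr": psnr,
        "psnr_capped": capped,
        "ssim": masked_ssim(ref, test, roi, data_range=peak),
        "mask_pixels": int((np.asarray(roi) > 0).sum()),
    }


@dataclass
class MetricReport:
    per_video: dict = field(default_factory=dict)  # name -> {psnr, ssim, mse, frames}
    psnr_mean: float = 0.0
    ssim_mean: float = 0.0
    mse_mean: float = 0.0
    any_psnr_capped: bool = False

    def to_dict(self) -> dict:
        return {
            "per_video": self.per_video,
            "PSNR_mean": self.psnr_mean,
            "SSIM_mean": self.ssim_mean,
            "MSE_mean": self.mse_mean,
            "any_psnr_capped": self.any_psnr_capped,
        }


def aggregate_report(per_frame_by_video: dict, frame_cap: int = FRAME_CAP_DEFAULT) -> MetricReport:
    """Two-level averaging: mean over frames within each video, then an
    unweighted mean over videos.  ``per_frame_by_video`` maps video name to a
    list of per-frame metric dicts (see :func:`frame_metrics`)."""
    if not per_frame_by_video:
        raise ValueError("no videos to aggregate")
    report = MetricReport()
    for name, frames in per_frame_by_video.items():
        if not frames:
            raise ValueError(f"video {name!r} has no frames")
        frames = frames[:frame_cap]
        report.per_video[name] = {
            "psnr": float(np.mean([f["psnr"] for f in frames])),
            "ssim": float(np.mean([f["ssim"] for f in frames])),
            "mse": float(np.mean([f["mse"] for f in frames])),
            "frames": len(frames),
        }
        report.any_psnr_capped |= any(f.get("psnr_capped", False) for f in frames)
    vids = list(report.per_video.values())
    report.psnr_mean = float(np.mean([v["psnr"] for v in vids]))
    report.ssim_mean = float(np.mean([v["ssim"] for v in vids]))
    report.mse_mean = float(np.mean([v["mse"] for v in vids]))
    return report


@dataclass
class DisparityEval:
    rms: float
    epe: float
    bad3: float  # percent of pixels with |error| > 3
    n_pixels: int
    occlusion_mode: str = "include"


def disparity_errors(est: np.ndarray, gt: np.ndarray, roi: np.ndarray,
                     occlusion_mask: np.ndarray | None = None,
                     mode: str = "include") -> DisparityEval:
    """RMS / EPE / Bad3% of a disparity estimate over the specular roi.

    ``mode`` 'include' evaluates all roi pixels, 'exclude' drops
    stereo-occluded pixels, 'occluded-only' keeps only them.
    """
    est = np.asarray(est, dtype=float)
    gt = np.asarray(gt, dtype=float)
    roi = np.asarray(roi) > 0
    region = roi.copy()
    if occlusion_mask is not None:
        occ = np.asarray(occlusion_mask) > 0
        if mode == "exclude":
            region &= ~occ
        elif mode == "occluded-only":
            region &= occ
        elif mode != "include":
            raise ValueError("mode must be include | exclude | occluded-only")
    if not region.any():
        raise ValueError("empty effective evaluation region")
    err = est[region] - gt[region]
    return DisparityEval(
        rms=float(np.sqrt(np.mean(err**2))),
        epe=float(np.mean(np.abs(err))),
        bad3=float(100.0 * np.mean(np.abs(err) > 3.0)),
        n_pixels=int(region.sum()),
        occlusion_mode=mode,
    )


def percent_delta(metric_orig: float, metric_inp: float):
    """Relative improvement in percent: 100*(orig - inp)/orig.

    Positive values mean inpainting reduced an error metric.  Returns
    (value, defined_flag); the value is nan when the original metric is 0.
    """
    if metric_orig == 0:
        return float("nan"), False
    return 100.0 * (metric_orig - metric_inp) / metric_orig, True
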