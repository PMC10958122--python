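"""End-to-end pipeline: synth -> detect -> pseudo -> inpaint -> evaluate -> downstream.

Each stage reads and writes only the documented on-disk formats (PNG frame
and mask directories, JSON reports), so stages can be rerun independently.
A provenance record (config, seed, stage list) accompanies every run;
reruns with the same configuration and seed produce identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from pathlib import Path

import numpy as np

from . import baselines, geometry, metrics, specmask, synthdata
from .frameio import RunConfig, read_frames, read_masks, write_frames, write_masks

STAGES = ("synth", "detect", "pseudo", "inpaint", "evaluate", "downstream")


class StageError(RuntimeError):
    """A stage's required upstream artifact is missing."""


def _dirs(cfg: RunConfig) -> dict:
    w = Path(cfg.workdir)
    return {
        "frames": w / "frames",
        "clean": w / "clean",
        "det_masks": w / "det_masks",
        "pseudo_masks": w / "pseudo_masks",
        "inpainted": w / "inpainted",
        "reports": w / "reports",
    }


def _require(path: Path, stage: str, needed_by: str):
    if not path.exists():
        raise StageError(
            f"stage {needed_by!r} needs {path} — run stage {stage!r} first"
        )


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Execute the requested stages in order; returns the report dict."""
    stages = [s for s in STAGES if s in set(stages)]
    d = _dirs(config)
    d["reports"].mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": stages, "seed": config.seed}

    if "synth" in stages:
        spec = synthdata.SyntheticSceneSpec(
            frame_count=config.frame_count, frame_size=config.frame_size,
            seed=config.seed,
        )
        clean, masks, corrupted = synthdata.generate_clip(spec)
        write_frames(corrupted, d["frames"])
        write_frames(clean, d["clean"])
        write_masks(masks, d["frames"].parent / "true_masks")

    if "detect" in stages:
        _require(d["frames"], "synth", "detect")
        frames = read_frames(d["frames"])
        params = specmask.DetectionParams(**config.detection)
        det = np.stack([specmask.detect_specular_mask(f, params) for f in frames])
        det = np.stack([specmask.dilate_mask(m, "diamond", 1) for m in det])
        write_masks(det, d["det_masks"])

    if "pseudo" in stages:
        _require(d["det_masks"], "detect", "pseudo")
        det = read_masks(d["det_masks"])
        spec = specmask.PseudoGTSpec(**config.pseudo)
        pseudo, translation = specmask.make_pseudo_mask_sequence(det, spec)
        write_masks(pseudo, d["pseudo_masks"])
        sidecar = {
            "translation": list(translation),
            "guard_radius": spec.guard_radius,
            "ellipse_radii": list(spec.ellipse_radii),
            "variant": spec.variant,
        }
        (d["pseudo_masks"] / "pseudo.json").write_text(json.dumps(sidecar, indent=2))

    if "inpaint" in stages:
        _require(d["frames"], "synth", "inpaint")
        _require(d["pseudo_masks"], "pseudo", "inpaint")
        frames = read_frames(d["frames"])
        masks = read_masks(d["pseudo_masks"])
        if config.inpaint_method == "diffusion":
            out = np.stack(
                [baselines.diffusion_inpaint(f, m) for f, m in zip(frames, masks)]
            )
        elif config.inpaint_method == "patch":
            out = baselines.temporal_patch_inpaint(frames, masks)
        elif config.inpaint_method == "model":
            from .sttn import inpaint_clip, load_checkpoint

            if not config.checkpoint:
                raise StageError("inpaint method 'model' needs a checkpoint path")
            state, _, _ = load_checkpoint(config.checkpoint)
            out = inpaint_clip(frames, masks, state)
        else:
            raise ValueError(f"unknown inpaint method {config.inpaint_method!r}")
        write_frames(out, d["inpainted"])

    if "evaluate" in stages:
        _require(d["inpainted"], "inpaint", "evaluate")
        _require(d["pseudo_masks"], "pseudo", "evaluate")
        ref = read_frames(d["frames"])[: config.eval_frame_cap]
        test = read_frames(d["inpainted"])[: config.eval_frame_cap]
        masks = read_masks(d["pseudo_masks"])[: config.eval_frame_cap]
        rows = []
        for f_ref, f_test, m in zip(ref, test, masks):
            if m.any():
                rows.append(metrics.frame_metrics(f_ref * 255, f_test * 255, m))
        rep = metrics.aggregate_report({"synthetic": rows},
                                       frame_cap=config.eval_frame_cap)
        report["evaluate"] = rep.to_dict()
        (d["reports"] / "metrics.json").write_text(
            json.dumps(report["evaluate"], indent=2)
        )

    if "downstream" in stages:
        # correspondence/pose check on a synthetic two-view scene with the
        # run's seed, plus disparity errors on a synthetic stereo pair
        scene = synthdata.generate_two_view_scene(
            100, rotation_deg=4.0, translation=(1.0, 0.1, 0.05),
            noise_px=0.0, seed=config.seed,
        )
        n = len(scene.proj_a)
        ms = geometry.MatchSet(
            scene.proj_a, scene.proj_b,
            np.column_stack([np.arange(n)] * 2), 1.0,
        )
        R, t, inl, degen = geometry.estimate_relative_pose(
            ms, scene.intrinsics, geometry.RansacParams(seed=config.seed)
        )
        spec = synthdata.SyntheticSceneSpec(
            frame_count=1, frame_size=config.frame_size, seed=config.seed
        )
        left, right, disp_gt = synthdata.generate_stereo_pair(
            spec, lambda rr, cc: 2.0 + 4.0 * cc / max(1, cc.max())
        )
        roi = np.zeros(disp_gt.shape, bool)
        roi[disp_gt.shape[0] // 4 : -disp_gt.shape[0] // 4,
            disp_gt.shape[1] // 4 : -disp_gt.shape[1] // 4] = True
        de = metrics.disparity_errors(disp_gt + 0.5, disp_gt, roi)
        report["downstream"] = {
            "pose": {
                "rre_deg": geometry.rotation_error(R, scene.rotation_gt),
                "rte_deg": geometry.translation_error(t, scene.translation_gt),
                "inliers": inl,
                "degenerate": degen,
            },
            "disparity": dataclasses.asdict(de),
        }
        (d["reports"] / "downstream.json").write_text(
            json.dumps(report["downstream"], indent=2)
        )

    prov = {
        "seed": config.seed,
        "stages": stages,
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: str(v) for k, v in sorted(config.__dict__.items())}
            ).encode()
        ).hexdigest()[:16],
    }
    (d["reports"] / "provenance.json").write_text(json.dumps(prov, indent=2))
    report["provenance"] = prov
    return report
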