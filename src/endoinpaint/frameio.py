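"""Frame/mask/video I/O and run configuration.

Conventions shared by every module: clips live in directories of
zero-padded 8-bit PNG frames (``00000.png`` ...), masks mirror the frame
names in a sibling directory as 8-bit PNG with 0 = valid and 255 = hole,
ground truth and reports are JSON, configuration is YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

__all__ = [
    "RunConfig",
    "read_frames",
    "write_frames",
    "read_masks",
    "write_masks",
    "extract_frames",
    "write_scene_json",
    "read_scene_json",
]


def write_frames(frames: np.ndarray, out_dir) -> Path:
    """Write a float [0,1] (or uint8) clip as %05d.png files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = np.asarray(frames)
    if frames.dtype != np.uint8:
        frames = (np.clip(frames, 0, 1) * 255.0).round().astype(np.uint8)
    for i, f in enumerate(frames):
        iio.imwrite(out / f"{i:05d}.png", f)
    return out


def read_frames(frame_dir, as_float: bool = True) -> np.ndarray:
    """Read a %05d.png frame directory into (T, H, W, 3)."""
    files = sorted(Path(frame_dir).glob("*.png"))
    if not files:
        raise FileNotFoundError(f"no PNG frames in {frame_dir}")
    frames = np.stack([iio.imread(f) for f in files])
    if frames.ndim == 3:
        frames = np.repeat(frames[..., None], 3, axis=3)
    frames = frames[..., :3]
    if as_float:
        return frames.astype(float) / 255.0
    return frames


def write_masks(masks: np.ndarray, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(np.asarray(masks)):
        iio.imwrite(out / f"{i:05d}.png", ((m > 0) * 255).astype(np.uint8))
    return out


def read_masks(mask_dir) -> np.ndarray:
    files = sorted(Path(mask_dir).glob("*.png"))
    if not files:
        raise FileNotFoundError(f"no PNG masks in {mask_dir}")
    masks = np.stack([iio.imread(f) for f in files])
    if masks.ndim == 4:
        masks = masks[..., 0]
    return (masks > 127).astype(np.uint8)


def extract_frames(video_file, fps: float = 24.0, out_dir=None) -> np.ndarray:
    """Extract frames from a video container at the requested rate.

    Requires an ffmpeg-capable imageio backend for mp4 input; raises a clear
    error when none is available.  When ``out_dir`` is given the frames are
    written as a %05d.png directory with a manifest JSON.
    """
    video_file = Path(video_file)
    if not video_file.exists():
        raise FileNotFoundError(video_file)
    try:
        meta = iio.immeta(video_file)
        frames = iio.imread(video_file)
    except Exception as exc:  # codec/backend missing
        raise RuntimeError(
            f"cannot decode {video_file.name}: no suitable imageio backend ({exc})"
        ) from exc
    src_fps = float(meta.get("fps", fps))
    if fps <= 0:
        raise ValueError("fps must be positive")
    step = max(1, int(round(src_fps / fps)))
    frames = np.asarray(frames)[::step]
    if out_dir is not None:
        write_frames(frames if frames.dtype == np.uint8 else frames.astype(np.uint8),
                     out_dir)
        manifest = {"source": str(video_file), "fps": fps, "count": int(len(frames))}
        (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return frames


def write_scene_json(path, intrinsics, rotation, translation, extra=None) -> None:
    d = {
        "intrinsics": np.asarray(intrinsics).reshape(-1).tolist(),  # row-major
        "rotation": np.asarray(rotation).reshape(-1).tolist(),
        "translation": np.asarray(translation).reshape(-1).tolist(),
    }
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2))


def read_scene_json(path):
    d = json.loads(Path(path).read_text())
    return (
        np.asarray(d["intrinsics"]).reshape(3, 3),
        np.asarray(d["rotation"]).reshape(3, 3),
        np.asarray(d["translation"]).reshape(3),
        d,
    )


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see docs for the YAML schema)."""

    workdir: str = "run"
    fps: float = 24.0
    eval_frame_cap: int = 927
    seed: int = 0
    frame_count: int = 24
    frame_size: tuple = (64, 64)
    detection: dict = field(default_factory=dict)
    pseudo: dict = field(default_factory=dict)
    inpaint_method: str = "diffusion"  # diffusion | patch | model
    checkpoint: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        extra = {k: v for k, v in d.items() if k not in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra.update(extra)
        if isinstance(cfg.frame_size, list):
            cfg.frame_size = tuple(cfg.frame_size)
        return cfg

    def to_yaml(self, path) -> None:
        d = dict(self.__dict__)
        d["frame_size"] = list(self.frame_size)
        Path(path).write_text(yaml.safe_dump(d))
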