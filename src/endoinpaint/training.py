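"""Losses, window sampling and the two-phase training loop.

The generator is optimised with a weighted sum of an L1 hole loss, an L1
valid-region loss and a hinge adversarial term
(L = l_hole * L_hole + l_valid * L_valid + l_adv * L_adv, with the
standard weights 1 / 1 / 0.01).  The discriminator is trained with the
hinge loss mean(ReLU(1 - D(real))) + mean(ReLU(1 + D(fake))).  Training
proceeds in two phases: an initialisation phase on temporally smooth
random (Bezier-trajectory) masks, followed by fine-tuning on the
pseudo-ground-truth specularity masks, transferring the weights between
phases.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .sttn import (
    DiscriminatorState,
    GeneratorState,
    TransformerConfig,
    discriminator_score,
    generator_forward,
    load_checkpoint,
    save_checkpoint,
)

__all__ = [
    "LossWeights",
    "TrainSchedule",
    "loss_hole",
    "loss_valid",
    "loss_adv",
    "loss_total",
    "loss_discriminator",
    "sample_training_window",
    "Adam",
    "train",
]


@dataclass
class LossWeights:
    lambda_hole: float = 1.0
    lambda_valid: float = 1.0
    lambda_adv: float = 0.01

    def __post_init__(self):
        if min(self.lambda_hole, self.lambda_valid, self.lambda_adv) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class TrainSchedule:
    """One training phase: 'init' (random masks) or 'finetune' (pseudo masks)."""

    phase: str = "init"
    iterations: int = 300
    batch: int = 1
    lr: float = 1e-4
    betas: tuple = (0.0, 0.99)
    checkpoint_every: int = 0  # 0 = only at the end
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    train_discriminator: bool = True

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.phase not in ("init", "finetune"):
            raise ValueError("phase must be 'init' or 'finetune'")


def _masked_l1(y, yhat, weight: np.ndarray):
    """||weight * (y - yhat)||_1 / ||weight||_1 over all pixels and channels."""
    wsum = float(np.sum(weight))
    if wsum == 0:
        raise ZeroDivisionError("normalising mask has zero L1 norm")
    if isinstance(yhat, Tensor) or isinstance(y, Tensor):
        y = y if isinstance(y, Tensor) else Tensor(np.asarray(y, float))
        yhat = yhat if isinstance(yhat, Tensor) else Tensor(np.asarray(yhat, float))
        diff = (y - yhat) * Tensor(weight)
        # weight has the channel axis broadcast in; the norm counts channels
        nch = y.data.shape[-1] if weight.shape != y.data.shape else 1
        return diff.abs().sum() * (1.0 / (wsum * nch))
    diff = np.abs(np.asarray(y, float) - np.asarray(yhat, float)) * weight
    nch = diff.shape[-1] if weight.shape != diff.shape else 1
    return float(diff.sum() / (wsum * nch))


def _broadcast_mask(m, ref) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    ref_shape = ref.data.shape if isinstance(ref, Tensor) else np.asarray(ref).shape
    if m.shape == ref_shape:
        return m
    if m.shape == ref_shape[:-1]:
        return m[..., None]
    raise ValueError("mask shape incompatible with frames")


def loss_hole(Y, Yhat, M):
    """Mean absolute error over hole pixels: ||M*(Y-Yhat)||_1 / ||M||_1."""
    m = _broadcast_mask(M, Y)
    return _masked_l1(Y, Yhat, m)


def loss_valid(Y, Yhat, M):
    """Mean absolute error over valid pixels: ||(1-M)*(Y-Yhat)||_1 / ||1-M||_1."""
    m = 1.0 - _broadcast_mask(M, Y)
    return _masked_l1(Y, Yhat, m)


def loss_adv(fake_scores):
    """Generator adversarial term: -mean(D(fake))."""
    if isinstance(fake_scores, Tensor):
        if fake_scores.data.size == 0:
            raise ValueError("empty score map")
        return -fake_scores.mean()
    s = np.asarray(fake_scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score map")
    return float(-s.mean())


def loss_total(Y, Yhat, M, fake_scores=None, w: LossWeights | None = None):
    """Weighted objective: l_hole*L_hole + l_valid*L_valid + l_adv*L_adv."""
    w = w or LossWeights()
    lh = loss_hole(Y, Yhat, M)
    lv = loss_valid(Y, Yhat, M)
    if fake_scores is None:
        la = 0.0
    else:
        la = loss_adv(fake_scores)
    total = lh * w.lambda_hole + lv * w.lambda_valid + la * w.lambda_adv
    return total


def loss_discriminator(real_scores, fake_scores):
    """Hinge loss: mean ReLU(1 - D(real)) + mean ReLU(1 + D(fake))."""
    def _hinge(scores, sign):
        if isinstance(scores, Tensor):
            if scores.data.size == 0:
                raise ValueError("empty score map")
            return (Tensor(np.ones_like(scores.data)) + scores * sign).relu().mean()
        s = np.asarray(scores, dtype=float)
        if s.size == 0:
            raise ValueError("empty score map")
        return float(np.mean(np.maximum(0.0, 1.0 + sign * s)))

    return _hinge(real_scores, -1.0) + _hinge(fake_scores, 1.0)


def sample_training_window(clip_len: int, target: int, n: int, s: int) -> list:
    """Conditioning index set for one target frame: clamp(t-n..t+n) plus
    distant frames {0, s, 2s, ...}, deduplicated and sorted (0-based)."""
    if not 0 <= target < clip_len:
        raise ValueError("target outside clip")
    lo, hi = max(0, target - n), min(clip_len - 1, target + n)
    idx = set(range(lo, hi + 1))
    idx.update(range(0, clip_len, s))
    return sorted(idx)


class Adam:
    """Adam over a name->Tensor parameter dict, with serialisable state."""

    def __init__(self, params: dict, lr: float = 1e-4, betas=(0.0, 0.99), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state_dict(self, d: dict):
        self.t = int(d["t"])
        self.m = {k: np.asarray(v) for k, v in d["m"].items()}
        self.v = {k: np.asarray(v) for k, v in d["v"].items()}


def _rng_state(rng: np.random.Generator) -> dict:
    return rng.bit_generator.state


def train(dataset, config: TransformerConfig, schedule: TrainSchedule,
          state: GeneratorState | None = None, dstate: DiscriminatorState | None = None,
          log_csv=None, checkpoint_path=None, resume=None):
    """Alternating generator/discriminator optimisation on (clip, masks) pairs.

    ``dataset`` is a sequence of (clip, masks) numpy pairs (clips in [0,1],
    masks 1 = hole) appropriate for the schedule's phase.  One master seed
    drives sampling; weight-init seeds are derived from it.  Returns
    ``(state, dstate, logs)`` with one log row per iteration.  With
    ``resume`` set to a checkpoint path, optimisation continues bitwise
    identically to an uninterrupted run.
    """
    w = schedule.weights
    adversarial = w.lambda_adv > 0 and schedule.train_discriminator
    ss = np.random.SeedSequence(schedule.seed)
    init_seed, disc_seed, _ = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    start_iter = 0
    g_opt_state = d_opt_state = None
    rng = np.random.default_rng(np.random.PCG64(schedule.seed))
    if resume is not None:
        state, dstate, header = load_checkpoint(resume)
        start_iter = int(header["iteration"])
        rng.bit_generator.state = header["rng_state"]
        g_opt_state = header.get("g_opt")
        d_opt_state = header.get("d_opt")
    else:
        if state is None:
            state = GeneratorState(config, seed=init_seed)
        if dstate is None and adversarial:
            dstate = DiscriminatorState(seed=disc_seed)
    g_opt = Adam(state.params, lr=schedule.lr, betas=schedule.betas)
    if g_opt_state is not None:
        g_opt.load_state_dict(_decode_opt(g_opt_state))
    d_opt = None
    if adversarial:
        d_opt = Adam(dstate.params, lr=schedule.lr, betas=schedule.betas)
        if d_opt_state is not None:
            d_opt.load_state_dict(_decode_opt(d_opt_state))

    logs = []
    for it in range(start_iter, schedule.iterations):
        row = {"iteration": it + 1, "L_hole": 0.0, "L_valid": 0.0,
               "L_adv": 0.0, "L_D": 0.0, "L_total": 0.0}
        state.zero_grad()
        fake_clips = []
        real_clips = []
        for _ in range(schedule.batch):
            ci = int(rng.integers(len(dataset)))
            clip, masks = dataset[ci]
            T = clip.shape[0]
            t = int(rng.integers(T))
            window = sample_training_window(T, t, config.neighbor_window,
                                            config.distant_rate)
            y = np.asarray(clip[window], dtype=float)
            m = np.asarray(masks[window], dtype=float)
            yhat = generator_forward(y, m, state, config)  # (T,3,H,W) in [-1,1]
            y_pm = Tensor(y.transpose(0, 3, 1, 2) * 2.0 - 1.0)
            m_ch = m[:, None, :, :]
            m_full = np.broadcast_to(m_ch, y_pm.shape).copy()
            lh = loss_hole(y_pm, yhat, m_full)
            lv = loss_valid(y_pm, yhat, m_full)
            la = None
            if adversarial:
                comp = y_pm * Tensor(1.0 - m_ch) + yhat * Tensor(m_ch)
                tw = comp.shape[0]
                comp5 = comp.transpose(1, 0, 2, 3).reshape(
                    1, 3, tw, comp.shape[2], comp.shape[3]
                )
                fake_scores = discriminator_score(comp5, dstate)
                la = loss_adv(fake_scores)
                fake_clips.append(comp.data.copy())
                real_clips.append(y_pm.data.copy())
            total = lh * w.lambda_hole + lv * w.lambda_valid
            if la is not None:
                total = total + la * w.lambda_adv
            total = total * (1.0 / schedule.batch)
            total.backward()
            row["L_hole"] += lh.item() / schedule.batch
            row["L_valid"] += lv.item() / schedule.batch
            row["L_adv"] += (la.item() if la is not None else 0.0) / schedule.batch
            row["L_total"] += total.item()
        if not np.isfinite(row["L_total"]):
            raise FloatingPointError(
                f"non-finite loss at iteration {it + 1}: {row}"
            )
        g_opt.step()

        if adversarial:
            dstate.zero_grad()
            dl_acc = 0.0
            for real, fake in zip(real_clips, fake_clips):
                rs = discriminator_score(
                    Tensor(real.transpose(1, 0, 2, 3)[None]), dstate
                )
                fs = discriminator_score(
                    Tensor(fake.transpose(1, 0, 2, 3)[None]), dstate
                )
                dl = loss_discriminator(rs, fs) * (1.0 / len(real_clips))
                dl.backward()
                dl_acc += dl.item()
            d_opt.step()
            row["L_D"] = dl_acc
        logs.append(row)

        want_ckpt = checkpoint_path is not None and (
            (schedule.checkpoint_every and (it + 1) % schedule.checkpoint_every == 0)
            or it + 1 == schedule.iterations
        )
        if want_ckpt:
            save_checkpoint(
                checkpoint_path, state, dstate,
                extra={
                    "iteration": it + 1,
                    "phase": schedule.phase,
                    "master_seed": schedule.seed,
                    "rng_state": _jsonable(_rng_state(rng)),
                    "g_opt": _encode_opt(g_opt.state_dict()),
                    "d_opt": _encode_opt(d_opt.state_dict()) if d_opt else None,
                },
            )
    if log_csv is not None:
        write_loss_log(log_csv, logs)
    return state, dstate, logs


def write_loss_log(path, logs) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.DictWriter(
            fh, fieldnames=["iteration", "L_hole", "L_valid", "L_adv", "L_D", "L_total"]
        )
        wr.writeheader()
        for row in logs:
            wr.writerow({k: row[k] for k in wr.fieldnames})


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return x


def _encode_opt(d: dict) -> dict:
    return {
        "t": d["t"],
        "m": {k: v.tolist() for k, v in d["m"].items()},
        "v": {k: v.tolist() for k, v in d["v"].items()},
    }


def _decode_opt(d: dict) -> dict:
    return {
        "t": d["t"],
        "m": {k: np.asarray(v) for k, v in d["m"].items()},
        "v": {k: np.asarray(v) for k, v in d["v"].items()},
    }
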