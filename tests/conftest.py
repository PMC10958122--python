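"""Shared fixtures: synthetic clips and a tiny overfit training run.

The overfit fixture trains the generator once per session (desk-scale
configuration, 8-frame 64x64 clip, adversarial term off) in three pieces —
a 150-iteration leg that writes a checkpoint, a resumed leg to 300, and an
uninterrupted 300-iteration run — so convergence, resume determinism and
the temporal-ablation comparison can all share the cost.
"""

import numpy as np
import pytest

from endoinpaint import synthdata
from endoinpaint.sttn import TransformerConfig
from endoinpaint.training import LossWeights, TrainSchedule, train

OVERFIT_SEED = 11
OVERFIT_TRAIN_SEED = 5


def overfit_clip_spec():
    return synthdata.SyntheticSceneSpec(
        frame_count=8,
        frame_size=(64, 64),
        seed=OVERFIT_SEED,
        highlight_params=synthdata.HighlightParams(
            count=3, radius_range=(4, 7), jump_prob=1.0
        ),
    )


def overfit_schedule(iterations: int) -> TrainSchedule:
    return TrainSchedule(
        phase="finetune",
        iterations=iterations,
        lr=2e-3,
        betas=(0.9, 0.99),
        seed=OVERFIT_TRAIN_SEED,
        weights=LossWeights(lambda_adv=0.0),
        train_discriminator=False,
    )


@pytest.fixture(scope="session")
def tiny_clip():
    """(clean, masks, corrupted): 8-frame clip whose highlights jump every
    frame, so every hole is visible in a neighbouring frame."""
    return synthdata.generate_clip(overfit_clip_spec())


@pytest.fixture(scope="session")
def overfit_run(tiny_clip, tmp_path_factory):
    """Train the tiny generator to overfit one clip; returns a dict with the
    trained state, the three loss logs and the checkpoint path."""
    clean, masks, _ = tiny_clip
    dataset = [(clean, masks)]
    config = TransformerConfig.tiny()
    ckpt = tmp_path_factory.mktemp("ckpt") / "mid.npz"

    state_a, _, logs_a = train(dataset, config, overfit_schedule(150),
                               checkpoint_path=str(ckpt))
    state_b, _, logs_b = train(dataset, config, overfit_schedule(300),
                               resume=str(ckpt))
    state_u, _, logs_u = train(dataset, config, overfit_schedule(300))
    return {
        "config": config,
        "state": state_b,
        "state_uninterrupted": state_u,
        "logs_first_leg": logs_a,
        "logs_resumed": logs_b,
        "logs_uninterrupted": logs_u,
        "checkpoint": ckpt,
    }
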