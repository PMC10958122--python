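"""Losses, window sampling, Adam, and the training loop."""

import csv

import numpy as np
import pytest

from endoinpaint.autodiff import Tensor
from endoinpaint.specmask import generate_bezier_random_masks
from endoinpaint.sttn import (DiscriminatorState, GeneratorState,
                              TransformerConfig, discriminator_score,
                              generator_forward)
from endoinpaint.training import (Adam, LossWeights, TrainSchedule, loss_adv,
                                  loss_discriminator, loss_hole, loss_total,
                                  loss_valid, sample_training_window, train,
                                  write_loss_log)


# -- loss identities ------------------------------------------------------


def test_hole_and_valid_losses_on_worked_example():
    # 2x2 single frame: hole covers the left column, error 0.5 in the hole
    # and 0.1 in the valid region
    Y = np.zeros((1, 2, 2, 1))
    Yhat = np.array([[[[0.5], [0.1]], [[0.5], [0.1]]]])
    M = np.array([[[1, 0], [1, 0]]], dtype=float)
    assert loss_hole(Y, Yhat, M) == pytest.approx(0.5, abs=1e-12)
    assert loss_valid(Y, Yhat, M) == pytest.approx(0.1, abs=1e-12)


def test_hole_loss_is_l1_normalised_by_mask_mass():
    rng = np.random.default_rng(0)
    Y = rng.random(size=(2, 4, 4, 3))
    Yhat = rng.random(size=(2, 4, 4, 3))
    M = (rng.random(size=(2, 4, 4)) > 0.5).astype(float)
    expect = np.abs(M[..., None] * (Y - Yhat)).sum() / (M.sum() * 3)
    assert loss_hole(Y, Yhat, M) == pytest.approx(expect, abs=1e-12)


def test_empty_mask_raises():
    Y = np.zeros((1, 2, 2, 3))
    with pytest.raises(ZeroDivisionError):
        loss_hole(Y, Y, np.zeros((1, 2, 2)))
    with pytest.raises(ZeroDivisionError):
        loss_valid(Y, Y, np.ones((1, 2, 2)))


def test_adversarial_and_total_loss_values():
    assert loss_adv(np.full((3, 2, 2), 0.5)) == pytest.approx(-0.5)
    Y = np.zeros((1, 2, 2, 1))
    Yhat = np.full((1, 2, 2, 1), 0.5)
    M = np.array([[[1, 0], [1, 0]]], dtype=float)
    # L = 1*0.5 + 1*0.5 + 0.01*(-0.5) = 0.995
    got = loss_total(Y, Yhat, M, fake_scores=np.full(4, 0.5))
    assert got == pytest.approx(0.995, abs=1e-12)


def test_discriminator_hinge_loss_values():
    # zero scores: ReLU(1-0) + ReLU(1+0) = 2
    assert loss_discriminator(np.zeros(5), np.zeros(5)) == pytest.approx(2.0)
    # perfectly separated scores beyond the margin: loss 0
    assert loss_discriminator(np.full(5, 2.0), np.full(5, -2.0)) == 0.0
    # Tensor path agrees
    t = loss_discriminator(Tensor(np.zeros(5)), Tensor(np.zeros(5)))
    assert t.item() == pytest.approx(2.0)


# -- window sampling ------------------------------------------------------


def test_training_window_examples():
    assert sample_training_window(30, 13, 2, 10) == [0, 10, 11, 12, 13, 14, 15, 20]
    assert sample_training_window(30, 0, 2, 10) == [0, 1, 2, 10, 20]
    assert sample_training_window(8, 7, 2, 10) == [0, 5, 6, 7]
    with pytest.raises(ValueError):
        sample_training_window(8, 8, 2, 10)


# -- optimiser ------------------------------------------------------------


def test_adam_single_step_matches_hand_computation():
    p = Tensor(np.array([1.0]), requires_grad=True)
    opt = Adam({"p": p}, lr=0.1, betas=(0.9, 0.99))
    p.grad = np.array([2.0])
    opt.step()
    m = 0.1 * 2.0 / (1 - 0.9)
    v = 0.01 * 4.0 / (1 - 0.99)
    expect = 1.0 - 0.1 * m / (np.sqrt(v) + 1e-8)
    assert p.data[0] == pytest.approx(expect, abs=1e-12)


# -- end-to-end gradient check --------------------------------------------


def _full_objective(state, dstate, y, m):
    T, H, W, _ = y.shape
    yhat = generator_forward(y, m, state)
    y_pm = Tensor(y.transpose(0, 3, 1, 2) * 2.0 - 1.0)
    m_ch = m[:, None, :, :]
    m_full = np.broadcast_to(m_ch, y_pm.data.shape).copy()
    lh = loss_hole(y_pm, yhat, m_full)
    lv = loss_valid(y_pm, yhat, m_full)
    comp = y_pm * Tensor(1.0 - m_ch) + yhat * Tensor(m_ch)
    comp5 = comp.transpose(1, 0, 2, 3).reshape(1, 3, T, H, W)
    la = loss_adv(discriminator_score(comp5, dstate))
    w = LossWeights()
    return lh * w.lambda_hole + lv * w.lambda_valid + la * w.lambda_adv


def test_full_objective_gradients_match_finite_differences():
    config = TransformerConfig.tiny((32, 32))
    state = GeneratorState(config, seed=2)
    dstate = DiscriminatorState(seed=3)
    rng = np.random.default_rng(4)
    y = rng.random(size=(3, 32, 32, 3))
    m = np.zeros((3, 32, 32))
    m[:, 8:20, 10:24] = 1.0

    state.zero_grad()
    dstate.zero_grad()
    loss = _full_objective(state, dstate, y, m)
    loss.backward()

    eps = 1e-5
    probes = [("enc1.w", (0, 0, 1, 1)), ("l0.h0.q.w", (2, 3, 0, 0)),
              ("l0.fuse2.w", (1, 1, 1, 1)), ("dec3.w", (0, 2, 0, 2)),
              ("dec3.b", (1,))]
    for name, idx in probes:
        p = state.params[name]
        orig = p.data[idx]
        p.data[idx] = orig + eps
        fp = _full_objective(state, dstate, y, m).item()
        p.data[idx] = orig - eps
        fm = _full_objective(state, dstate, y, m).item()
        p.data[idx] = orig
        num = (fp - fm) / (2 * eps)
        ana = p.grad[idx]
        denom = max(abs(num), abs(ana), 1e-8)
        assert abs(num - ana) / denom <= 1e-4, (name, idx, num, ana)


# -- training loop --------------------------------------------------------


def test_adversarial_training_runs_and_logs(tmp_path):
    config = TransformerConfig.tiny((32, 32))
    rng = np.random.default_rng(7)
    clip = rng.random(size=(5, 32, 32, 3))
    masks = generate_bezier_random_masks(5, (32, 32), seed=1, shape_radius=(4, 7))
    schedule = TrainSchedule(phase="init", iterations=3, seed=0)
    csv_path = tmp_path / "loss.csv"
    state, dstate, logs = train([(clip, masks)], config, schedule,
                                log_csv=str(csv_path))
    assert dstate is not None  # adversarial phase trains the discriminator
    assert len(logs) == 3
    for row in logs:
        assert all(np.isfinite(row[k]) for k in
                   ("L_hole", "L_valid", "L_adv", "L_D", "L_total"))
        assert row["L_D"] != 0.0
    with open(csv_path) as fh:
        rows = list(csv.DictReader(fh))
    assert [int(r["iteration"]) for r in rows] == [1, 2, 3]
    assert float(rows[0]["L_hole"]) == pytest.approx(logs[0]["L_hole"])


def test_training_reduces_hole_loss(overfit_run):
    logs = overfit_run["logs_uninterrupted"]
    first = np.mean([r["L_hole"] for r in logs[:10]])
    last = np.mean([r["L_hole"] for r in logs[-10:]])
    assert last < 0.5 * first


def test_resumed_run_matches_uninterrupted_logs(overfit_run):
    full = overfit_run["logs_first_leg"] + overfit_run["logs_resumed"]
    ref = overfit_run["logs_uninterrupted"]
    assert [r["iteration"] for r in full] == [r["iteration"] for r in ref]
    for a, b in zip(full, ref):
        assert a["L_hole"] == b["L_hole"]
        assert a["L_total"] == b["L_total"]
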