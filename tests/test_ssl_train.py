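"""SSL training: EMA oracle, self-distillation loss closed forms, segmentation
loss oracle, step identities, checkpoint round trips."""

import numpy as np
import pytest

from conftest import tiny_run_config
from msssl import nn
from msssl.augment import AugmentConfig, make_view_pair
from msssl.nn import Tensor
from msssl.ssl_train import (
    LossReport,
    SSLState,
    init_state,
    load_checkpoint,
    match_loss,
    momentum_update,
    prepare_samples,
    pretrain,
    pretrain_step,
    save_checkpoint,
    seg_loss,
    update_center,
)


def make_state(m=0.9, ts=0.1, tt=0.04, lam=1.0, proj_dim=4):
    """A lightweight SSLState shell for loss-level tests (no networks)."""
    dummy = nn.Linear(2, 2, np.random.default_rng(0))
    return SSLState(student=dummy, teacher=dummy, center=np.zeros(proj_dim, np.float32),
                    momentum=m, student_temp=ts, teacher_temp=tt, lambda_seg=lam)


# -- momentum update ----------------------------------------------------------

@pytest.mark.parametrize("m", [0.0, 0.5, 0.9, 0.996, 1.0])
def test_momentum_update_matches_convex_combination_oracle(m, tiny_cfg):
    state = init_state(tiny_cfg)
    state.momentum = m
    rng = np.random.default_rng(4)
    for p in state.student.parameters():
        p.data = rng.standard_normal(p.data.shape).astype(np.float32)
    s_before = {k: v.copy() for k, v in state.student.state_dict().items()}
    t_before = {k: v.copy() for k, v in state.teacher.state_dict().items()}
    momentum_update(state)
    for name, t_new in state.teacher.state_dict().items():
        expected = np.empty_like(t_new)
        flat_t, flat_s = t_before[name].ravel(), s_before[name].ravel()
        out = np.array([m * t + (1 - m) * s for t, s in zip(flat_t, flat_s)], np.float32)
        np.testing.assert_allclose(t_new.ravel(), out, rtol=1e-5, atol=1e-6)
    # student untouched
    for name, s_new in state.student.state_dict().items():
        np.testing.assert_array_equal(s_new, s_before[name])


# -- match loss ---------------------------------------------------------------

def test_match_loss_uniform_equals_log_k():
    state = make_state(proj_dim=4)
    loss = match_loss(np.zeros(4, np.float32), np.zeros(4, np.float32), state)
    assert abs(float(loss.data) - np.log(4.0)) < 1e-6


def test_match_loss_matches_explicit_cross_entropy(rng):
    state = make_state(proj_dim=8)
    state.center = rng.standard_normal(8).astype(np.float32) * 0.1
    s = rng.standard_normal((5, 8)).astype(np.float32)
    t = rng.standard_normal((5, 8)).astype(np.float32)
    loss = float(match_loss(s, t, state).data)
    # hand-rolled oracle
    total = 0.0
    for i in range(5):
        lt = (t[i] - state.center) / state.teacher_temp
        p = np.exp(lt - lt.max())
        p /= p.sum()
        ls = s[i] / state.student_temp
        q = np.exp(ls - ls.max())
        q /= q.sum()
        total += -(p * np.log(q)).sum()
    assert abs(loss - total / 5) < 1e-4


def test_match_loss_minimized_when_student_matches_teacher(rng):
    # gradient descent on student logits approaches the entropy of the
    # (sharpened) teacher target — the cross-entropy lower bound
    state = make_state(ts=0.5, tt=0.25)
    t = rng.standard_normal(4).astype(np.float32)
    lt = t / state.teacher_temp
    p = np.exp(lt - lt.max())
    p /= p.sum()
    entropy = -(p * np.log(p)).sum()
    logits = Tensor(np.zeros((1, 4), np.float32), requires_grad=True)
    for _ in range(800):
        loss = match_loss(logits, t[None], state)
        logits.grad = None
        loss.backward()
        logits.data = logits.data - 0.5 * logits.grad
    assert float(loss.data) - entropy < 1e-3


def test_match_loss_errors():
    state = make_state()
    with pytest.raises(ValueError):
        match_loss(np.zeros(3), np.zeros(4), state)
    with pytest.raises(FloatingPointError):
        match_loss(np.array([np.nan, 0.0]), np.zeros(2), state)


# -- segmentation loss ----------------------------------------------------------

def test_seg_loss_perfect_prediction_limit(rng):
    mask = (rng.uniform(size=(8, 8)) < 0.4).astype(np.float32)
    logits = (mask * 2 - 1) * 20.0  # +-20 logits: probabilities ~ mask
    assert float(seg_loss(logits, mask).data) < 1e-3


def test_seg_loss_constant_field_closed_form():
    # all-zero mask, zero logits: BCE = ln 2 per pixel; Dice = 1 - eps/(sum p + eps)
    mask = np.zeros((4, 4), np.float32)
    logits = np.zeros((4, 4), np.float32)
    val = float(seg_loss(logits, mask, eps=1.0).data)
    expected = np.log(2.0) + (1.0 - 1.0 / (0.5 * 16 + 1.0))
    assert abs(val - expected) < 1e-5


def test_seg_loss_matches_per_pixel_loop(rng):
    logits = rng.standard_normal((5, 5)).astype(np.float32)
    mask = (rng.uniform(size=(5, 5)) < 0.5).astype(np.float32)
    val = float(seg_loss(logits, mask, eps=1.0).data)
    bce = 0.0
    inter = psum = zsum = 0.0
    for i in range(5):
        for j in range(5):
            x, z = logits[i, j], mask[i, j]
            p = 1 / (1 + np.exp(-x))
            bce += -(z * np.log(p) + (1 - z) * np.log(1 - p))
            inter += p * z
            psum += p
            zsum += z
    expected = bce / 25 + (1 - (2 * inter + 1) / (psum + zsum + 1))
    assert abs(val - expected) < 1e-4


def test_seg_loss_shape_mismatch():
    with pytest.raises(ValueError):
        seg_loss(np.zeros((4, 4), np.float32), np.zeros((5, 5), np.float32))


# -- step-level properties ----------------------------------------------------

@pytest.fixture(scope="module")
def tiny_batch(small_dataset, tiny_cfg):
    images, _ = small_dataset
    samples = prepare_samples(images, "fine_grained")
    aug = AugmentConfig(crop_size=64, mean=(0.5,) * 3, std=(0.5,) * 3)
    g = np.random.default_rng(2)
    return [make_view_pair(s.raster, s.mask, aug, g, source_id=s.source_id)
            for s in samples[:8]]


def test_loss_report_identity():
    rep = LossReport(match_loss=2.0, seg_loss=0.5, lambda_seg=0.3)
    assert rep.total == 2.0 + 0.3 * 0.5


def test_pretrain_step_identity_and_teacher_ema(tiny_batch, tiny_cfg):
    state = init_state(tiny_cfg)
    t_old = {k: v.copy() for k, v in state.teacher.state_dict().items()}
    report = pretrain_step(tiny_batch, state, lr=1e-4)
    assert report.total == report.match_loss + report.lambda_seg * report.seg_loss
    m = state.momentum
    s_new = state.student.state_dict()
    # EMA oracle applied post-optimizer-step
    for name, t_new in state.teacher.state_dict().items():
        np.testing.assert_allclose(t_new, m * t_old[name] + (1 - m) * s_new[name],
                                   rtol=1e-5, atol=1e-6)
    # drift bound: |delta teacher| <= (1-m) max|teacher - student| pre-update
    deltas, bounds = [], []
    for name in t_old:
        deltas.append(np.abs(state.teacher.state_dict()[name] - t_old[name]).max())
        bounds.append(np.abs(t_old[name] - s_new[name]).max())
    assert max(deltas) <= (1 - m) * max(bounds) + 1e-6


def test_no_negative_pairs(tiny_batch, tiny_cfg):
    """Per-sample losses never depend on other batch elements."""
    state = init_state(tiny_cfg)
    xa = Tensor(np.stack([vp.view_a for vp in tiny_batch[:4]]))
    with nn.no_grad():
        t = state.teacher.project(xa).data
        s = state.student.project(xa).data
    per = match_loss(Tensor(s), t, state, reduction="none").data
    dup = np.concatenate([s, s[:1]], axis=0)
    tdup = np.concatenate([t, t[:1]], axis=0)
    per_dup = match_loss(Tensor(dup), tdup, state, reduction="none").data
    np.testing.assert_allclose(per, per_dup[:4], rtol=1e-6)


def test_center_is_convex_combination_of_teacher_projections():
    state = make_state(proj_dim=3)
    state.center_momentum = 0.9
    observed = []
    rng = np.random.default_rng(0)
    for _ in range(50):
        batch = rng.standard_normal((4, 3)).astype(np.float32)
        observed.append(batch.mean(axis=0))
        update_center(state, batch)
    # EMA recursion: center = sum_i c_i * mean_i with c_i >= 0, sum <= 1
    coeffs = np.array([0.1 * 0.9 ** (len(observed) - 1 - i) for i in range(len(observed))])
    expected = (coeffs[:, None] * np.array(observed)).sum(axis=0)
    np.testing.assert_allclose(state.center, expected, rtol=1e-4, atol=1e-5)
    assert coeffs.min() >= 0 and coeffs.sum() <= 1.0 + 1e-9


def test_lambda_zero_leaves_seg_head_ungraded(tiny_batch, tiny_cfg):
    state = init_state(tiny_cfg)
    state.lambda_seg = 0.0
    state.optimizer = None  # inspect gradients without applying them
    pretrain_step(tiny_batch, state)
    for p in state.student.dle.seg_conv.parameters():
        assert p.grad is None or np.abs(p.grad).max() == 0.0


def test_pretrain_step_requires_masks(tiny_batch, tiny_cfg):
    state = init_state(tiny_cfg)
    broken = [type(tiny_batch[0])(view_a=vp.view_a, view_b=vp.view_b,
                                  source_id=vp.source_id, mask_a=None, mask_b=None)
              for vp in tiny_batch]
    with pytest.raises(ValueError, match="mask"):
        pretrain_step(broken, state)


# -- checkpointing --------------------------------------------------------------

def test_checkpoint_roundtrip_is_bit_exact(tmp_path, small_dataset):
    images, _ = small_dataset
    cfg = tiny_run_config(ssl=dict(batch_size=4, epochs=1), data=dict(n_per_grade=4))
    res = pretrain(images, cfg, out_dir=tmp_path)
    state = res["state"]
    loaded, meta = load_checkpoint(res["checkpoint"], cfg)
    for name, p in state.student.state_dict().items():
        np.testing.assert_array_equal(p, loaded.student.state_dict()[name])
    for name, p in state.teacher.state_dict().items():
        np.testing.assert_array_equal(p, loaded.teacher.state_dict()[name])
    np.testing.assert_array_equal(state.center, loaded.center)
    assert loaded.step == state.step
    assert meta["config_digest"] == cfg.digest()


def test_checkpoint_digest_mismatch_rejected(tmp_path, small_dataset):
    images, _ = small_dataset
    cfg = tiny_run_config(ssl=dict(batch_size=4, epochs=1), data=dict(n_per_grade=4))
    res = pretrain(images, cfg, out_dir=tmp_path)
    other = tiny_run_config(ssl=dict(batch_size=4, epochs=1), data=dict(n_per_grade=4),
                            encoder=dict(embed_dim=32, num_heads=4))
    with pytest.raises(ValueError, match="digest"):
        load_checkpoint(res["checkpoint"], other)


def test_resume_reproduces_uninterrupted_run(tmp_path, small_dataset):
    images, _ = small_dataset
    cfg = tiny_run_config(ssl=dict(batch_size=8, epochs=2, checkpoint_every=1),
                          data=dict(n_per_grade=4))
    full = pretrain(images, cfg, out_dir=tmp_path / "full")
    # resume epoch 2 from the full run's epoch-0 checkpoint
    resumed = pretrain(images, cfg, out_dir=tmp_path / "resumed",
                       resume_from=tmp_path / "full" / "checkpoint_ep000.npz")
    steps_per_epoch = len(full["history"]) // 2
    full_tail = [(r["step"], r["total"]) for r in full["history"][steps_per_epoch:]]
    res_hist = [(r["step"], r["total"]) for r in resumed["history"][steps_per_epoch:]]
    assert full_tail == res_hist
    for name, p in full["state"].student.state_dict().items():
        np.testing.assert_array_equal(p, resumed["state"].student.state_dict()[name])
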