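"""Momentum-encoder self-supervised pretraining with two objectives.

A student network (MFEE -> Deep Learner, with a projection head on the ViT
global token and a segmentation head on the Deep Learner output) is trained
against a momentum teacher — a structural copy whose parameters follow the
student by exponential moving average and through which no gradient flows.

Two losses are combined per step:

* **representation matching** — self-distillation: the cross-entropy between
  the teacher's centered, temperature-sharpened softmax and the student's
  softmax, symmetrized over the two augmented views. Centering (an EMA of
  teacher projections) plus sharpening prevents collapse without negative
  pairs.
* **segmentation** — binary cross-entropy plus soft Dice between the
  student's segmentation logits and the saliency-derived binary mask, which
  steers the features toward the salient retinal regions.

``total = match + lambda_seg * seg`` holds as an exact identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .augment import AugmentConfig, make_view_pair
from .config import RunConfig, substream
from .deep_learner import DeepLearner, DLeConfig
from .mfee import (
    MultiScaleFusion,
    ProjectionHead,
    ResNetFPN,
    TokenEmbeddings,
    ViTEncoder,
)
from .nn import Tensor
from .preprocess import binarize_saliency, compute_saliency, extract_green_channel, green_unit_raster


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

class MsSSLNet(nn.Module):
    """Student/teacher network: GFE + FFE + fusion + DLe + heads."""

    def __init__(self, cfg: RunConfig, rng: np.random.Generator):
        enc = cfg.encoder
        self.gfe = ViTEncoder(cfg.vit_config(), rng)
        self.ffe = ResNetFPN(enc.fpn_backbone, rng, base_width=enc.resnet_width,
                             fpn_channels=enc.fpn_channels)
        self.fusion = MultiScaleFusion(self.gfe.cfg.embed_dim, enc.fpn_channels, rng,
                                       method=enc.fusion)
        fused_ch = (6 if enc.fusion == "concatenation" else 3) * enc.fpn_channels
        self.dle = DeepLearner(fused_ch, DLeConfig(
            layer_kind=cfg.dle.layer_kind,
            attention_position=cfg.dle.attention_position,
            n_stages=cfg.dle.n_stages,
            kernel=cfg.dle.kernel,
        ), rng, cbam_reduction=cfg.dle.cbam_reduction)
        self.proj_head = ProjectionHead(self.gfe.cfg.embed_dim, rng,
                                        hidden_dim=enc.proj_hidden, out_dim=enc.proj_dim)
        self.proj_dim = enc.proj_dim

    def gfe_tokens(self, x, store_attention: bool = False) -> TokenEmbeddings:
        return self.gfe(x, store_attention=store_attention)

    def project(self, x) -> Tensor:
        """SSL projection of the global token (the teacher's whole job)."""
        return self.proj_head(self.gfe_tokens(x).global_token)

    def forward_full(self, x):
        """Student forward: projection + segmentation logits."""
        data = x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))
        h, w = data.shape[2], data.shape[3]
        emb = self.gfe_tokens(data)
        pyr = self.ffe(data)
        fused = self.fusion(pyr, emb)
        dle_out = self.dle(fused, (h, w))
        proj = self.proj_head(emb.global_token)
        return proj, dle_out.seg_logits, emb

    def pooled_representation(self, x, representation: str = "full") -> Tensor:
        """Representation for downstream heads (differentiable).

        ``gfe``: the ViT global token after the final layer norm.
        ``full``: that token concatenated with the spatially averaged Deep
        Learner features — the multi-scale path the framework exists for.
        """
        data = x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))
        emb = self.gfe_tokens(data)
        if representation == "gfe":
            return emb.global_token
        if representation != "full":
            raise ValueError(f"unknown representation {representation!r}")
        pyr = self.ffe(data)
        fused = self.fusion(pyr, emb)
        dle_out = self.dle(fused, (data.shape[2], data.shape[3]))
        pooled = dle_out.features.mean(axis=(2, 3))
        return nn.cat([emb.global_token, pooled], axis=1)

    def representation_dim(self, representation: str = "full") -> int:
        d = self.gfe.cfg.embed_dim
        return d if representation == "gfe" else d + self.dle.out_channels

    def embed(self, x, representation: str = "full") -> np.ndarray:
        """Pooled representation as a plain array (no tape)."""
        with nn.no_grad():
            return np.ascontiguousarray(self.pooled_representation(x, representation).data)


def build_student_teacher(cfg: RunConfig, rng: np.random.Generator):
    student = MsSSLNet(cfg, rng)
    teacher = MsSSLNet(cfg, np.random.default_rng(0))
    teacher.load_state_dict(student.state_dict())  # start as an exact copy
    return student, teacher


# ---------------------------------------------------------------------------
# state and losses
# ---------------------------------------------------------------------------

@dataclass
class SSLState:
    student: MsSSLNet
    teacher: MsSSLNet
    center: np.ndarray
    momentum: float = 0.996
    student_temp: float = 0.1
    teacher_temp: float = 0.04
    center_momentum: float = 0.9
    lambda_seg: float = 1.0
    step: int = 0
    optimizer: nn.AdamW | None = None

    def __post_init__(self):
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError("momentum must be in [0, 1]")
        if not self.teacher_temp < self.student_temp:
            raise ValueError("teacher_temp must be < student_temp")
        self.center = np.asarray(self.center, np.float32)


@dataclass
class LossReport:
    match_loss: float
    seg_loss: float
    lambda_seg: float
    total: float = field(init=False)

    def __post_init__(self):
        self.total = self.match_loss + self.lambda_seg * self.seg_loss


def momentum_update(state: SSLState) -> SSLState:
    """teacher <- m * teacher + (1 - m) * student, elementwise; the student
    is untouched and no gradient ever flows through the teacher."""
    s_params = dict(state.student.named_parameters())
    t_params = dict(state.teacher.named_parameters())
    if set(s_params) != set(t_params):
        raise ValueError("student/teacher parameter structures differ")
    m = state.momentum
    for name, tp in t_params.items():
        sp = s_params[name]
        if tp.data.shape != sp.data.shape:
            raise ValueError(f"shape mismatch at {name}")
        tp.data = m * tp.data + (1.0 - m) * sp.data
    return state


def match_loss(student_proj, teacher_proj, state: SSLState, reduction: str = "mean") -> Tensor:
    """Self-distillation cross-entropy for one (student, teacher) direction.

    Teacher target: softmax((teacher_proj - center) / teacher_temp), a
    constant. Student: log-softmax(student_proj / student_temp). The step
    symmetrizes by calling this twice with crossed views.
    """
    s = student_proj if isinstance(student_proj, Tensor) else Tensor(np.asarray(student_proj, np.float32))
    t = teacher_proj.data if isinstance(teacher_proj, Tensor) else np.asarray(teacher_proj, np.float32)
    if s.shape[-1] != t.shape[-1]:
        raise ValueError("projection dimensions differ")
    if not np.isfinite(s.data).all() or not np.isfinite(t).all():
        raise FloatingPointError("non-finite projection; step aborted")
    if s.ndim == 1:
        s = s.reshape(1, -1)
        t = t.reshape(1, -1)
    logits_t = (t - state.center) / state.teacher_temp
    logits_t = logits_t - logits_t.max(axis=-1, keepdims=True)
    e = np.exp(logits_t)
    p = e / e.sum(axis=-1, keepdims=True)  # constant target
    logq = nn.log_softmax(s * (1.0 / state.student_temp), axis=-1)
    per_sample = -(Tensor(p) * logq).sum(axis=-1)
    if reduction == "none":
        return per_sample
    return per_sample.mean()


def update_center(state: SSLState, teacher_projs: np.ndarray) -> None:
    """EMA of observed teacher projections (collapse-prevention centering)."""
    batch_mean = np.asarray(teacher_projs, np.float32).reshape(-1, state.center.shape[0]).mean(axis=0)
    cm = state.center_momentum
    state.center = cm * state.center + (1.0 - cm) * batch_mean


def _abs(x: Tensor) -> Tensor:
    return x.relu() + (-x).relu()


def seg_loss(seg_logits, mask, eps: float = 1.0, reduction: str = "mean") -> Tensor:
    """Binary cross-entropy plus soft Dice (equal weights, smoothing eps)."""
    x = seg_logits if isinstance(seg_logits, Tensor) else Tensor(np.asarray(seg_logits, np.float32))
    z = np.asarray(mask.values if hasattr(mask, "values") else mask, np.float32)
    if x.ndim == 2:
        x = x.reshape(1, 1, *x.shape)
    if z.ndim == 2:
        z = z[None, None]
    elif z.ndim == 3:
        z = z[:, None]
    if x.shape != z.shape:
        raise ValueError(f"seg_logits shape {x.shape} does not match mask {z.shape}")
    zt = Tensor(z)
    n = x.shape[0]
    # numerically stable BCE-with-logits: max(x,0) - x*z + log(1 + exp(-|x|))
    bce = x.relu() - x * zt + (1.0 + (-_abs(x)).exp()).log()
    bce = bce.reshape(n, -1).mean(axis=-1)
    p = x.sigmoid().reshape(n, -1)
    zf = zt.reshape(n, -1)
    inter = (p * zf).sum(axis=-1)
    dice = 1.0 - (2.0 * inter + eps) / (p.sum(axis=-1) + zf.sum(axis=-1) + eps)
    per_sample = bce + dice
    if reduction == "none":
        return per_sample
    return per_sample.mean()


# ---------------------------------------------------------------------------
# training step
# ---------------------------------------------------------------------------

def pretrain_step(view_pairs, state: SSLState, lr: float | None = None) -> LossReport:
    """One optimizer step on the student from a batch of augmented view
    pairs (masks required), followed by the teacher EMA update."""
    if any(vp.mask_a is None or vp.mask_b is None for vp in view_pairs):
        raise ValueError("pretrain_step requires masks on every view pair")
    xa = Tensor(np.stack([vp.view_a for vp in view_pairs]))
    xb = Tensor(np.stack([vp.view_b for vp in view_pairs]))
    ma = np.stack([vp.mask_a for vp in view_pairs]).astype(np.float32)
    mb = np.stack([vp.mask_b for vp in view_pairs]).astype(np.float32)

    with nn.no_grad():
        t_a = state.teacher.project(xa).data
        t_b = state.teacher.project(xb).data
    if not (np.isfinite(t_a).all() and np.isfinite(t_b).all()):
        raise FloatingPointError("non-finite teacher projection; step aborted")

    proj_a, seg_a, _ = state.student.forward_full(xa)
    proj_b, seg_b, _ = state.student.forward_full(xb)

    match = (match_loss(proj_a, t_b, state) + match_loss(proj_b, t_a, state)) * 0.5
    if state.lambda_seg > 0:
        seg = (seg_loss(seg_a, ma) + seg_loss(seg_b, mb)) * 0.5
        total = match + state.lambda_seg * seg
    else:
        with nn.no_grad():
            seg = (seg_loss(Tensor(seg_a.data), ma) + seg_loss(Tensor(seg_b.data), mb)) * 0.5
        total = match
    if not np.isfinite(total.data).all():
        raise FloatingPointError("non-finite loss; step aborted")

    state.student.zero_grad()
    total.backward()
    if state.optimizer is not None:
        if lr is not None:
            state.optimizer.lr = lr
        state.optimizer.step()
        state.optimizer.zero_grad()
    momentum_update(state)
    update_center(state, np.concatenate([t_a, t_b], axis=0))
    state.step += 1
    return LossReport(match_loss=float(match.data), seg_loss=float(seg.data),
                      lambda_seg=state.lambda_seg)


# ---------------------------------------------------------------------------
# dataset preparation and the epoch loop
# ---------------------------------------------------------------------------

@dataclass
class PreparedSample:
    raster: np.ndarray        # (3, H, W) float32 in [0, 1]
    mask: np.ndarray          # (H, W) uint8
    source_id: str
    partner: "PreparedSample | None" = None  # other view of the same eye


def prepare_samples(images, saliency_method: str = "fine_grained") -> list[PreparedSample]:
    """Green channel + saliency mask for every image; dual views of one eye
    are linked as partners."""
    samples = []
    by_id: dict[str, PreparedSample] = {}
    for img in images:
        green = extract_green_channel(img)
        mask = binarize_saliency(compute_saliency(green, saliency_method))
        s = PreparedSample(raster=green_unit_raster(green), mask=mask.values,
                           source_id=img.id)
        if img.view in ("left", "right"):
            if img.id in by_id:
                s.partner = by_id[img.id]
                by_id[img.id].partner = s
            else:
                by_id[img.id] = s
        samples.append(s)
    return samples


def _pair_views(sample: PreparedSample, aug_cfg: AugmentConfig, rng, dual_pair_prob: float):
    if sample.partner is not None and rng.uniform() < dual_pair_prob:
        return make_view_pair(sample.raster, sample.mask, aug_cfg, rng,
                              source_id=sample.source_id,
                              img_b=sample.partner.raster, mask_b=sample.partner.mask)
    return make_view_pair(sample.raster, sample.mask, aug_cfg, rng, source_id=sample.source_id)


def init_state(cfg: RunConfig, seed: int | None = None) -> SSLState:
    rng = substream("init", seed=seed if seed is not None else cfg.runtime.seed)
    student, teacher = build_student_teacher(cfg, rng)
    opt = nn.AdamW(student.parameters(), lr=cfg.ssl.lr, weight_decay=cfg.ssl.weight_decay)
    return SSLState(
        student=student, teacher=teacher,
        center=np.zeros(cfg.encoder.proj_dim, np.float32),
        momentum=cfg.ssl.momentum, student_temp=cfg.ssl.student_temp,
        teacher_temp=cfg.ssl.teacher_temp, center_momentum=cfg.ssl.center_momentum,
        lambda_seg=cfg.ssl.lambda_seg, optimizer=opt,
    )


def pretrain(images, cfg: RunConfig, out_dir=None, resume_from=None,
             log_callback=None) -> dict:
    """Run the pretraining epochs; returns {'state', 'history', 'checkpoint'}.

    Deterministic given cfg.runtime.seed: data order, pairing and
    augmentation draw from per-(seed, epoch, batch) substreams, so a run
    resumed from an epoch checkpoint reproduces the uninterrupted run
    exactly.
    """
    if not images:
        raise ValueError("dataset is empty")
    seed = cfg.runtime.seed
    samples = prepare_samples(images, cfg.preprocess.saliency)
    aug_cfg = AugmentConfig(
        crop_size=cfg.augment.crop_size, flip_prob=cfg.augment.flip_prob,
        brightness=cfg.augment.brightness, contrast=cfg.augment.contrast,
        saturation=cfg.augment.saturation, hue=cfg.augment.hue,
        blur_kernels=cfg.augment.blur_kernels, blur_prob=cfg.augment.blur_prob,
        crop_scale=cfg.augment.crop_scale,
        mean=(cfg.preprocess.mean,) * 3, std=(cfg.preprocess.std,) * 3,
    )
    bs = cfg.ssl.batch_size
    steps_per_epoch = max(1, len(samples) // bs)
    total_steps = steps_per_epoch * cfg.ssl.epochs
    start_epoch = 0
    history: list[dict] = []
    if resume_from is not None:
        state, meta = load_checkpoint(resume_from, cfg)
        start_epoch = int(meta["epoch"]) + 1
        history = list(meta.get("history", []))
    else:
        state = init_state(cfg, seed)
    ckpt_path = None
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for epoch in range(start_epoch, cfg.ssl.epochs):
        order = substream("order", epoch, seed=seed).permutation(len(samples))
        for b in range(steps_per_epoch):
            idx = order[b * bs:(b + 1) * bs]
            rng = substream("augment", epoch, b, seed=seed)
            pairs = [_pair_views(samples[i], aug_cfg, rng, cfg.ssl.dual_pair_prob) for i in idx]
            lr = nn.cosine_lr(cfg.ssl.lr, epoch * steps_per_epoch + b, total_steps)
            report = pretrain_step(pairs, state, lr=lr)
            rec = {"step": state.step, "epoch": epoch, "total": report.total,
                   "match": report.match_loss, "seg": report.seg_loss,
                   "lr": lr, "m": state.momentum}
            history.append(rec)
            if log_callback is not None:
                log_callback(rec)
        if out is not None and ((epoch + 1) % cfg.ssl.checkpoint_every == 0
                                or epoch == cfg.ssl.epochs - 1):
            ckpt_path = out / f"checkpoint_ep{epoch:03d}.npz"
            save_checkpoint(state, ckpt_path, cfg, epoch=epoch, history=history)
    if out is not None:
        with open(out / "train_log.jsonl", "w") as fh:
            for rec in history:
                fh.write(json.dumps(rec) + "\n")
    return {"state": state, "history": history, "checkpoint": ckpt_path}


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(state: SSLState, path, cfg: RunConfig, epoch: int = -1,
                    history: list | None = None) -> None:
    path = Path(path)
    arrays = {}
    for name, p in state.student.named_parameters():
        arrays[f"student/{name}"] = p.data
    for name, p in state.teacher.named_parameters():
        arrays[f"teacher/{name}"] = p.data
    arrays["center"] = state.center
    if state.optimizer is not None:
        opt = state.optimizer.state_dict()
        arrays["opt/t"] = np.asarray([opt["t"]], np.int64)
        for i, (m, v) in enumerate(zip(opt["m"], opt["v"])):
            arrays[f"opt/m/{i}"] = m
            arrays[f"opt/v/{i}"] = v
    np.savez_compressed(path, **arrays)
    sidecar = {
        "config": json.loads(cfg.canonical()),
        "config_digest": cfg.digest(),
        "structure_digest": cfg.structure_digest(),
        "step": state.step,
        "epoch": epoch,
        "seed": cfg.runtime.seed,
        "history": history or [],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path, cfg: RunConfig | None = None) -> tuple[SSLState, dict]:
    """Rebuild an SSLState from a checkpoint archive and its JSON sidecar.

    When ``cfg`` is given its digest must match the one recorded at save
    time — a checkpoint is never loaded into a structurally different model.
    """
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if cfg is None:
        cfg = RunConfig(**meta["config"])
    elif cfg.structure_digest() != meta["structure_digest"]:
        raise ValueError("checkpoint/config structure digest mismatch: refusing "
                         "to load into a structurally different model")
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    state = init_state(cfg, meta.get("seed", cfg.runtime.seed))
    state.student.load_state_dict(
        {k.split("/", 1)[1]: v for k, v in arrays.items() if k.startswith("student/")})
    state.teacher.load_state_dict(
        {k.split("/", 1)[1]: v for k, v in arrays.items() if k.startswith("teacher/")})
    state.center = arrays["center"].astype(np.float32)
    state.step = int(meta["step"])
    if "opt/t" in arrays and state.optimizer is not None:
        n = len(list(state.student.parameters()))
        state.optimizer.load_state_dict({
            "t": int(arrays["opt/t"][0]),
            "m": [arrays[f"opt/m/{i}"] for i in range(n)],
            "v": [arrays[f"opt/v/{i}"] for i in range(n)],
        })
    return state, meta
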