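"""Downstream evaluation: splits, linear probing, fine-tuning, metrics,
attention visualization.

Grading diabetic retinopathy is an ordinal 5-class problem, so the headline
metric is the quadratic weighted kappa

    kappa = 1 - sum_ij w_ij O_ij / sum_ij w_ij E_ij,   w_ij = (i-j)^2/(K-1)^2,

with O the observed contingency counts and E the outer product of the
marginals scaled to the sample size: disagreements are penalized by the
squared grade distance, and chance agreement is corrected for.

Linear evaluation trains only a (multinomial logistic) linear head on the
frozen pooled representation — the ViT global token after the final layer
norm — measuring representation quality; fine-tuning adapts every parameter,
measuring transferability. Model selection uses validation kappa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion

from . import nn
from .config import RunConfig, substream
from .mfee import ViTEncoder
from .nn import Tensor
from .preprocess import extract_green_channel, normalize_for_model
from .ssl_train import MsSSLNet, SSLState, load_checkpoint
from .synthetic import FundusImage


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    fractions: tuple = (0.70, 0.15, 0.15)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        f = tuple(float(x) for x in self.fractions)
        if len(f) != 3 or any(x <= 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("fractions must be three positives summing to 1")
        self.fractions = f


def _split_ids(ids: np.ndarray, fractions, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(ids)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test  # remainder goes to train
    perm = rng.permutation(n)
    return (ids[perm[:n_train]], ids[perm[n_train:n_train + n_val]],
            ids[perm[n_train + n_val:]])


def split_dataset(manifest: pd.DataFrame, spec: SplitSpec):
    """Disjoint, exhaustive train/val/test partition of a manifest.

    Splits operate on unique image ids (all views of a dual-view eye land in
    the same split). Stratified mode partitions within each grade.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    rng = np.random.default_rng(spec.seed)
    uniq = manifest.drop_duplicates("id")[["id", "grade"]]
    if spec.stratified:
        trains, vals, tests = [], [], []
        for grade, group in uniq.groupby("grade", sort=True):
            if len(group) < 3:
                raise ValueError(f"grade {grade} has fewer than 3 samples; "
                                 "cannot stratify")
            tr, va, te = _split_ids(group["id"].to_numpy(), spec.fractions, rng)
            trains.append(tr)
            vals.append(va)
            tests.append(te)
        tr = np.concatenate(trains)
        va = np.concatenate(vals)
        te = np.concatenate(tests)
    else:
        tr, va, te = _split_ids(uniq["id"].to_numpy(), spec.fractions, rng)
    parts = tuple(manifest[manifest["id"].isin(set(s))].reset_index(drop=True)
                  for s in (tr, va, te))
    return parts


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def quadratic_weighted_kappa(y_true, y_pred, k: int = 5) -> float:
    yt = np.asarray(y_true, np.int64)
    yp = np.asarray(y_pred, np.int64)
    if yt.size == 0:
        raise ValueError("empty label vectors")
    if yt.shape != yp.shape:
        raise ValueError("label vectors must have equal length")
    if yt.min() < 0 or yt.max() >= k or yp.min() < 0 or yp.max() >= k:
        raise ValueError(f"labels must lie in 0..{k - 1}")
    observed = np.zeros((k, k), np.float64)
    np.add.at(observed, (yt, yp), 1.0)
    n = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
    i, j = np.indices((k, k))
    w = (i - j) ** 2 / (k - 1) ** 2
    denom = (w * expected).sum()
    if denom == 0.0:
        return 1.0  # both raters constant on the same class
    return float(1.0 - (w * observed).sum() / denom)


@dataclass
class MetricsReport:
    kappa: float
    accuracy: float           # percent
    f1_weighted: float        # percent
    f1_macro: float
    f1_micro: float
    confusion: np.ndarray     # (5, 5) counts, rows = truth

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa, "accuracy": self.accuracy,
            "f1_weighted": self.f1_weighted, "f1_macro": self.f1_macro,
            "f1_micro": self.f1_micro, "confusion": self.confusion.tolist(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def classification_metrics(y_true, y_pred, k: int = 5) -> MetricsReport:
    from sklearn.metrics import accuracy_score, f1_score

    yt = np.asarray(y_true, np.int64)
    yp = np.asarray(y_pred, np.int64)
    if yt.shape != yp.shape:
        raise ValueError("label vectors must have equal length")
    labels = list(range(k))
    return MetricsReport(
        kappa=quadratic_weighted_kappa(yt, yp, k),
        accuracy=100.0 * accuracy_score(yt, yp),
        f1_weighted=100.0 * f1_score(yt, yp, labels=labels, average="weighted", zero_division=0),
        f1_macro=100.0 * f1_score(yt, yp, labels=labels, average="macro", zero_division=0),
        f1_micro=100.0 * f1_score(yt, yp, labels=labels, average="micro", zero_division=0),
        confusion=_sk_confusion(yt, yp, labels=labels),
    )


# ---------------------------------------------------------------------------
# representations
# ---------------------------------------------------------------------------

def _image_raster(img: FundusImage, input_size: int, mean: float, std: float) -> np.ndarray:
    pixels = img.pixels
    if pixels.shape[0] != input_size or pixels.shape[1] != input_size:
        pixels = np.asarray(Image.fromarray(pixels).resize((input_size, input_size),
                                                           Image.BILINEAR))
    return normalize_for_model(extract_green_channel(FundusImage(pixels, img.id)),
                               mean=mean, std=std)


def _resolve_state(checkpoint, cfg: RunConfig | None) -> tuple[SSLState, RunConfig]:
    if isinstance(checkpoint, SSLState):
        if cfg is None:
            raise ValueError("cfg is required when passing an SSLState")
        return checkpoint, cfg
    state, meta = load_checkpoint(checkpoint, cfg)
    return state, (cfg or RunConfig(**meta["config"]))


def extract_features(state: SSLState, images, cfg: RunConfig,
                     batch_size: int = 32) -> np.ndarray:
    """Pooled representations for a list of images (frozen encoder)."""
    rasters = [
        _image_raster(img, cfg.encoder.input_size, cfg.preprocess.mean, cfg.preprocess.std)
        for img in images
    ]
    feats = []
    for i in range(0, len(rasters), batch_size):
        feats.append(state.student.embed(np.stack(rasters[i:i + batch_size]),
                                         cfg.eval.representation))
    return np.concatenate(feats, axis=0)


def _select_images(images, manifest: pd.DataFrame):
    by_key = {}
    for img in images:
        by_key.setdefault(img.id, []).append(img)
    selected, labels = [], []
    for _, row in manifest.iterrows():
        for img in by_key.get(row["id"], []):
            if img.view == row["view"] or row["view"] == "single":
                selected.append(img)
                labels.append(int(row["grade"]))
    return selected, np.asarray(labels, np.int64)


def linear_eval(checkpoint, images, splits, cfg: RunConfig | None = None,
                seed: int = 0, shuffle_labels: bool = False) -> MetricsReport:
    """Linear evaluation: a multinomial logistic head on the frozen pooled
    representation; the regularization strength is selected by validation
    kappa; metrics are reported on the held-out test split.

    ``splits`` is the (train, val, test) manifest triple. The encoder is
    verified bit-identical before and after (frozen contract).
    """
    state, cfg = _resolve_state(checkpoint, cfg)
    digest_before = state.student.param_digest()
    train_m, val_m, test_m = splits
    xs, ys = {}, {}
    for name, m in (("train", train_m), ("val", val_m), ("test", test_m)):
        imgs, labels = _select_images(images, m)
        xs[name] = extract_features(state, imgs, cfg)
        ys[name] = labels
    if shuffle_labels:
        # null pipeline: the labels available to training (train + model
        # selection) carry no information about the images; test truth intact
        g = np.random.default_rng(seed)
        ys["train"] = g.permutation(ys["train"])
        ys["val"] = g.permutation(ys["val"])
    # standardize features on train statistics (the usual linear-probe recipe)
    mu = xs["train"].mean(axis=0)
    sd = xs["train"].std(axis=0) + 1e-8
    for name in xs:
        xs[name] = (xs[name] - mu) / sd
    best = None
    for c in (0.01, 0.1, 1.0, 10.0):
        head = LogisticRegression(C=c, max_iter=2000, random_state=seed)
        head.fit(xs["train"], ys["train"])
        val_kappa = quadratic_weighted_kappa(ys["val"], head.predict(xs["val"]))
        if best is None or val_kappa > best[0]:
            best = (val_kappa, head)
    head = best[1]
    if state.student.param_digest() != digest_before:
        raise RuntimeError("encoder parameters changed during linear evaluation")
    return classification_metrics(ys["test"], head.predict(xs["test"]))


def finetune(checkpoint, images, splits, cfg: RunConfig | None = None,
             seed: int = 0, epochs: int | None = None) -> MetricsReport:
    """Fine-tuning: a linear head on the pooled representation with every
    encoder parameter trainable; best epoch selected by validation kappa.

    ``epochs=0`` evaluates the freshly initialized head without any update.
    """
    state, cfg = _resolve_state(checkpoint, cfg)
    if epochs is None:
        epochs = cfg.eval.epochs
    train_m, val_m, test_m = splits
    data = {}
    for name, m in (("train", train_m), ("val", val_m), ("test", test_m)):
        imgs, labels = _select_images(images, m)
        rasters = np.stack([
            _image_raster(img, cfg.encoder.input_size, cfg.preprocess.mean, cfg.preprocess.std)
            for img in imgs
        ])
        data[name] = (rasters, labels)
    rng = substream("finetune-head", seed=seed)
    student = state.student
    repr_kind = cfg.eval.representation
    head = nn.Linear(student.representation_dim(repr_kind), 5, rng, std=0.01)

    def predict(split: str, batch: int = 32) -> np.ndarray:
        xs, _ = data[split]
        out = []
        with nn.no_grad():
            for i in range(0, len(xs), batch):
                rep = student.pooled_representation(Tensor(xs[i:i + batch]), repr_kind)
                out.append(head(rep).data.argmax(axis=1))
        return np.concatenate(out)

    def snapshot():
        return {"student": student.state_dict(), "head": head.state_dict()}

    best = (quadratic_weighted_kappa(data["val"][1], predict("val"))
            if len(data["val"][1]) else -np.inf, snapshot())
    if epochs > 0:
        params = list(student.parameters()) + list(head.parameters())
        opt = nn.AdamW(params, lr=cfg.eval.lr, weight_decay=0.0)
        xs, ys = data["train"]
        bs = min(32, len(xs))
        order_rng = substream("finetune-order", seed=seed)
        for ep in range(epochs):
            order = order_rng.permutation(len(xs))
            for i in range(0, len(xs) - bs + 1, bs):
                idx = order[i:i + bs]
                rep = student.pooled_representation(Tensor(xs[idx]), repr_kind)
                logits = head(rep)
                logq = nn.log_softmax(logits, axis=-1)
                loss = -logq[np.arange(len(idx)), ys[idx]].mean()
                for p in params:
                    p.grad = None
                loss.backward()
                opt.step()
            val_kappa = quadratic_weighted_kappa(data["val"][1], predict("val"))
            if val_kappa > best[0]:
                best = (val_kappa, snapshot())
        student.load_state_dict(best[1]["student"])
        head.load_state_dict(best[1]["head"])
    return classification_metrics(data["test"][1], predict("test"))


# ---------------------------------------------------------------------------
# attention visualization
# ---------------------------------------------------------------------------

@dataclass
class AttentionMapResult:
    grid: np.ndarray          # (H/p, W/p) in [0, 1]
    source_layer: str = "last"
    aggregation: str = "mean"
    token: str = "global"


def attention_map(checkpoint, img: FundusImage, cfg: RunConfig | None = None,
                  resolution: int = 1024, overlay_path=None) -> AttentionMapResult:
    """Last-layer global-token self-attention of the ViT, head-averaged.

    The image is resized to ``resolution`` (1024 by default, for a detailed
    grid), encoded, and the final layer's attention row of the global token
    (self-entry dropped) is averaged over heads, reshaped to the patch grid
    and min-max normalized.
    """
    if isinstance(checkpoint, ViTEncoder):
        vit, mean, std = checkpoint, 0.5, 0.5
    else:
        state, cfg = _resolve_state(checkpoint, cfg)
        vit, mean, std = state.student.gfe, cfg.preprocess.mean, cfg.preprocess.std
    p = vit.cfg.patch_size
    if resolution % p:
        raise ValueError(f"patch size {p} must divide the resolution {resolution}")
    pixels = np.asarray(Image.fromarray(img.pixels).resize((resolution, resolution),
                                                           Image.BILINEAR))
    raster = normalize_for_model(extract_green_channel(FundusImage(pixels, img.id)),
                                 mean=mean, std=std)
    with nn.no_grad():
        emb = vit(raster[None], store_attention=True)
    attn = emb.attentions[-1][0]          # (heads, 1+P, 1+P)
    row = attn[:, 0, 1:]                  # global-token row, self-entry dropped
    grid_side = resolution // p
    g = row.mean(axis=0).reshape(grid_side, grid_side)
    lo, hi = g.min(), g.max()
    g = np.zeros_like(g) if hi - lo < 1e-12 else (g - lo) / (hi - lo)
    if overlay_path is not None:
        _save_overlay(pixels, g, overlay_path)
    return AttentionMapResult(grid=g)


def _save_overlay(pixels: np.ndarray, grid: np.ndarray, path) -> None:
    heat = np.asarray(Image.fromarray((grid * 255).astype(np.uint8)).resize(
        (pixels.shape[1], pixels.shape[0]), Image.BILINEAR), np.float64) / 255.0
    overlay = pixels.astype(np.float64)
    overlay[:, :, 0] = np.clip(overlay[:, :, 0] + 120.0 * heat, 0, 255)
    Image.fromarray(overlay.astype(np.uint8)).save(path)
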