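"""Run configuration: YAML loading, validation, defaults, determinism.

The defaults reproduce the framework's best ablation settings: fine-grained
saliency, ResNet50 FPN backbone, ViT-S with patch 16, element-wise-addition
fusion, transposed-convolution Deep Learner stages with CBAM at the end.
Unknown keys and out-of-range enum values are rejected with the offending
path in the error message. A canonical serialized form and its SHA-256
digest bind checkpoints to the configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataCfg(_Block):
    dir: Optional[str] = None           # directory of PNG/JPEG + manifest.csv
    image_size: int = Field(default=224, ge=64)
    n_per_grade: int = Field(default=60, ge=1)
    lesion_rates: tuple[float, float, float, float, float] = (0.0, 2.0, 5.0, 10.0, 20.0)
    dual_view: bool = False
    retina_radius_frac: float = Field(default=0.92, gt=0.0, le=1.0)


class PreprocessCfg(_Block):
    saliency: Literal["spectral", "fine_grained"] = "fine_grained"
    crop_threshold: int = Field(default=10, ge=0, le=255)
    mean: float = 0.5
    std: float = 0.5


class AugmentCfg(_Block):
    crop_size: int = Field(default=224, ge=32)
    flip_prob: float = Field(default=0.5, ge=0.0, le=1.0)
    brightness: float = 0.4
    contrast: float = 0.4
    saturation: float = 0.4
    hue: float = 0.1
    blur_kernels: tuple[int, ...] = (3, 5, 7)
    blur_prob: float = 0.5
    crop_scale: tuple[float, float] = (0.3, 1.0)


class EncoderCfg(_Block):
    vit_variant: Literal["S", "B"] = "S"
    patch_size: Literal[16, 32] = 16
    # explicit overrides for desk-scale models; None means use the variant preset
    embed_dim: Optional[int] = None
    depth: Optional[int] = None
    num_heads: Optional[int] = None
    fpn_backbone: Literal["resnet18", "resnet50"] = "resnet50"
    fpn_channels: int = Field(default=256, ge=8)
    resnet_width: int = Field(default=64, ge=8)
    fusion: Literal["addition", "concatenation", "multiplication"] = "addition"
    input_size: int = Field(default=224, ge=64)
    proj_hidden: int = Field(default=2048, ge=8)
    proj_dim: int = Field(default=256, ge=4)

    @model_validator(mode="after")
    def _divisible(self):
        if self.input_size % self.patch_size:
            raise ValueError("encoder.input_size must be divisible by encoder.patch_size")
        if self.input_size % 32:
            raise ValueError("encoder.input_size must be divisible by 32")
        return self


class DleCfg(_Block):
    layer_kind: Literal["conv1d", "conv2d", "transposed2d"] = "transposed2d"
    attention_position: Literal["none", "first", "last"] = "last"
    n_stages: int = Field(default=2, ge=1)
    kernel: int = 3
    cbam_reduction: int = Field(default=16, ge=1)


class SSLCfg(_Block):
    momentum: float = Field(default=0.996, ge=0.0, le=1.0)
    student_temp: float = Field(default=0.1, gt=0.0)
    teacher_temp: float = Field(default=0.04, gt=0.0)
    center_momentum: float = Field(default=0.9, ge=0.0, le=1.0)
    lambda_seg: float = Field(default=1.0, ge=0.0)
    lr: float = Field(default=5e-4, gt=0.0)
    weight_decay: float = Field(default=0.04, ge=0.0)
    epochs: int = Field(default=5, ge=1)
    batch_size: int = Field(default=8, ge=1)
    dual_pair_prob: float = Field(default=0.5, ge=0.0, le=1.0)
    checkpoint_every: int = Field(default=1, ge=1)

    @model_validator(mode="after")
    def _temps(self):
        if not self.teacher_temp < self.student_temp:
            raise ValueError("ssl.teacher_temp must be < ssl.student_temp (target sharpening)")
        return self


class EvalCfg(_Block):
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    stratified: bool = True
    seed: int = 0
    representation: Literal["gfe", "full"] = "full"
    epochs: int = Field(default=20, ge=0)
    lr: float = Field(default=1e-3, gt=0.0)

    @model_validator(mode="after")
    def _fractions(self):
        if any(f <= 0 for f in self.fractions) or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("eval.fractions must be positive and sum to 1")
        return self


class RuntimeCfg(_Block):
    seed: int = 0
    deterministic: bool = True
    out_dir: str = "runs"


class RunConfig(_Block):
    data: DataCfg = DataCfg()
    preprocess: PreprocessCfg = PreprocessCfg()
    augment: AugmentCfg = AugmentCfg()
    encoder: EncoderCfg = EncoderCfg()
    dle: DleCfg = DleCfg()
    ssl: SSLCfg = SSLCfg()
    eval: EvalCfg = EvalCfg()
    runtime: RuntimeCfg = RuntimeCfg()

    # -- canonical form -----------------------------------------------------
    def canonical(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True, separators=(",", ":"))

    def digest(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()

    def structure_digest(self) -> str:
        """Digest of the blocks that define model structure (encoder + DLe
        + preprocess); checkpoints bind to this, so schedule-only changes
        (epochs, lr) stay loadable while shape changes are refused."""
        payload = json.dumps(
            {"encoder": self.encoder.model_dump(mode="json"),
             "dle": self.dle.model_dump(mode="json"),
             "preprocess": self.preprocess.model_dump(mode="json")},
            sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(payload.encode()).hexdigest()

    def vit_config(self):
        from .mfee import VIT_PRESETS, ViTConfig

        d, depth, h = VIT_PRESETS[self.encoder.vit_variant]
        return ViTConfig(
            input_size=self.encoder.input_size,
            patch_size=self.encoder.patch_size,
            embed_dim=self.encoder.embed_dim or d,
            depth=self.encoder.depth or depth,
            num_heads=self.encoder.num_heads or h,
        )


def load_config(path) -> RunConfig:
    """Load, default and validate a YAML run configuration.

    An empty file yields the full default configuration.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a YAML mapping")
    return RunConfig(**data)


def config_from_dict(data: dict | None = None, **overrides) -> RunConfig:
    merged = dict(data or {})
    merged.update(overrides)
    return RunConfig(**merged)


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

_ROOT_SEED = 0
_DETERMINISTIC = True


def set_global_determinism(seed: int, deterministic: bool = True) -> None:
    """Fix the root seed from which all named substreams derive."""
    global _ROOT_SEED, _DETERMINISTIC
    _ROOT_SEED = int(seed)
    _DETERMINISTIC = bool(deterministic)
    np.random.seed(_ROOT_SEED % (2 ** 32))


def substream(name: str, *indices: int, seed: int | None = None) -> np.random.Generator:
    """A named, reproducible RNG substream fanned out from the root seed."""
    root = _ROOT_SEED if seed is None else int(seed)
    key = f"{root}:{name}:" + ":".join(str(i) for i in indices)
    h = hashlib.sha256(key.encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "little"))


def root_seed() -> int:
    return _ROOT_SEED
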