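"""Deep Learner (DLe): staged learned upsampling of the fused features.

The fused multi-scale map (at the P2 resolution) is refined through stages of
transposed 3x3 convolutions (stride 2, padding 1, output padding 1 — each
stage exactly doubles the spatial side) with rectifier nonlinearities,
optionally gated by a Convolutional Block Attention Module (CBAM) before the
first stage or after the last. Same-resolution 2-D and flattened 1-D
convolution stacks are provided as ablation paths. A 1x1 convolution on the
final features followed by a bilinear resize to the image resolution yields
the segmentation logits consumed by the self-supervised segmentation
objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

LAYER_KINDS = ("conv1d", "conv2d", "transposed2d")
ATTENTION_POSITIONS = ("none", "first", "last")


@dataclass
class DLeConfig:
    layer_kind: str = "transposed2d"
    attention_position: str = "last"
    n_stages: int = 2
    kernel: int = 3

    def __post_init__(self):
        if self.layer_kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer_kind {self.layer_kind!r}; expected one of {LAYER_KINDS}")
        if self.attention_position not in ATTENTION_POSITIONS:
            raise ValueError(
                f"unknown attention_position {self.attention_position!r}; "
                f"expected one of {ATTENTION_POSITIONS}"
            )
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")


@dataclass
class DeepLearnerOutput:
    features: Tensor   # refined map; side = input side * 2^n_stages for transposed2d
    seg_logits: Tensor  # (N, 1, H_img, W_img)


class CBAM(nn.Module):
    """Convolutional Block Attention Module.

    Channel attention: per-channel spatial average- and max-pooled
    descriptors pass through a shared two-layer perceptron (reduction ratio
    r), are summed and squashed by a logistic; the result scales each
    channel. Spatial attention: channel-wise mean and max maps are stacked,
    convolved 7x7 and squashed; the result scales each pixel. Channel
    attention is applied first, then spatial.
    """

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 16):
        if channels < reduction:
            raise ValueError(f"CBAM needs at least {reduction} channels, got {channels}")
        hidden = channels // reduction
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)
        self.spatial_conv = nn.Conv2d(2, 1, 7, rng, pad=3)

    def channel_gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3))           # (N, C)
        mx = x.max(axis=3).max(axis=2)      # (N, C)
        att = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        n, c = att.shape
        return att.sigmoid().reshape(n, c, 1, 1)

    def spatial_gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.spatial_conv(nn.cat([avg, mx], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        x = x * self.channel_gate(x)
        return x * self.spatial_gate(x)


def _stage_channels(in_ch: int, n_stages: int) -> list[int]:
    # halve per stage (floor), never below 32
    chans = []
    c = in_ch
    for _ in range(n_stages):
        c = max(32, c // 2)
        chans.append(c)
    return chans


class DeepLearner(nn.Module):
    """Refinement trunk + segmentation head over a fused feature map."""

    def __init__(self, in_channels: int, cfg: DLeConfig, rng: np.random.Generator,
                 cbam_reduction: int = 16):
        self.cfg = cfg
        chans = _stage_channels(in_channels, cfg.n_stages)
        self.stages = nn.ModuleList()
        prev = in_channels
        for c in chans:
            if cfg.layer_kind == "transposed2d":
                self.stages.append(
                    nn.ConvTranspose2d(prev, c, cfg.kernel, rng, stride=2, pad=1, output_pad=1)
                )
            elif cfg.layer_kind == "conv2d":
                self.stages.append(nn.Conv2d(prev, c, cfg.kernel, rng, pad=cfg.kernel // 2))
            else:  # conv1d over the flattened spatial axis, per channel
                self.stages.append(
                    nn.Conv2d(prev, c, (1, cfg.kernel), rng, pad=(0, cfg.kernel // 2))
                )
            prev = c
        self.out_channels = prev
        if cfg.attention_position == "first":
            self.cbam = CBAM(in_channels, rng, reduction=cbam_reduction)
        elif cfg.attention_position == "last":
            self.cbam = CBAM(prev, rng, reduction=cbam_reduction)
        else:
            self.cbam = None
        self.seg_conv = nn.Conv2d(prev, 1, 1, rng)

    def _trunk(self, x: Tensor) -> Tensor:
        flat = self.cfg.layer_kind == "conv1d"
        if flat:
            n, c, h, w = x.shape
            hw = (h, w)
            x = x.reshape(n, c, 1, h * w)
        for stage in self.stages:
            x = stage(x).relu()
        if flat:
            n, c = x.shape[0], x.shape[1]
            x = x.reshape(n, c, hw[0], hw[1])
        return x

    def forward(self, fused, image_size: int | tuple[int, int]) -> DeepLearnerOutput:
        x = fused.values if hasattr(fused, "values") else fused
        if self.cfg.attention_position == "first":
            x = self.cbam(x)
        x = self._trunk(x)
        if self.cfg.attention_position == "last":
            x = self.cbam(x)
        if isinstance(image_size, int):
            image_size = (image_size, image_size)
        seg = nn.bilinear_resize(self.seg_conv(x), image_size[0], image_size[1])
        return DeepLearnerOutput(features=x, seg_logits=seg)


def dle_forward(fused, cfg: DLeConfig, rng: np.random.Generator | None = None,
                image_size: int | None = None, module: DeepLearner | None = None) -> DeepLearnerOutput:
    """Functional wrapper: build (or reuse) a DeepLearner and run it."""
    x = fused.values if hasattr(fused, "values") else fused
    if module is None:
        if rng is None:
            rng = np.random.default_rng(0)
        module = DeepLearner(x.shape[1], cfg, rng)
    if image_size is None:
        scale = 2 ** cfg.n_stages if cfg.layer_kind == "transposed2d" else 1
        image_size = x.shape[2] * scale
    return module(fused, image_size)
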