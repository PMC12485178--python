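"""Multi-scale Feature Extraction Encoder (MFEE).

Two complementary branches look at the same image:

* the **Global Feature Extractor (GFE)** — a vision transformer whose
  self-attention captures long-range, image-wide context; and
* the **Fine-grained Feature Extractor (FFE)** — a ResNet backbone with a
  Feature Pyramid Network (FPN) whose P2/P3/P5 levels (strides 4/8/32)
  retain local detail at multiple scales.

The FFE levels are brought to the P2 resolution and concatenated; the GFE
patch tokens are reshaped to their grid, linearly projected to the same
channel width and resized; the two stacks are then combined by element-wise
addition (default), channel concatenation, or element-wise multiplication.
The fused map feeds the Deep Learner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

VIT_PRESETS = {  # embed_dim, depth, heads — the standard ViT-S / ViT-B recipes
    "S": (384, 12, 6),
    "B": (768, 12, 12),
}

FUSION_METHODS = ("addition", "concatenation", "multiplication")


@dataclass
class ViTConfig:
    """Vision-transformer hyperparameters.

    ``from_variant`` covers the four standard variants (S/B x patch 16/32);
    explicit dimensions allow desk-scale models.
    """

    input_size: int = 224
    patch_size: int = 16
    embed_dim: int = 384
    depth: int = 12
    num_heads: int = 6
    mlp_ratio: int = 4

    @classmethod
    def from_variant(cls, variant: str, patch_size: int = 16, input_size: int = 224) -> "ViTConfig":
        if variant not in VIT_PRESETS:
            raise ValueError(f"unknown ViT variant {variant!r}; expected one of {sorted(VIT_PRESETS)}")
        if patch_size not in (16, 32):
            raise ValueError(f"patch_size must be 16 or 32, got {patch_size}")
        d, depth, h = VIT_PRESETS[variant]
        return cls(input_size=input_size, patch_size=patch_size, embed_dim=d, depth=depth, num_heads=h)

    def __post_init__(self):
        if self.input_size % self.patch_size:
            raise ValueError(
                f"input_size {self.input_size} not divisible by patch_size {self.patch_size}"
            )
        if self.embed_dim % self.num_heads:
            raise ValueError("embed_dim must be divisible by num_heads")


@dataclass
class TokenEmbeddings:
    """ViT output: tokens (N, 1+P, D) with the global token first."""

    tokens: Tensor
    grid: tuple[int, int]
    attentions: list  # per layer: np.ndarray (N, heads, 1+P, 1+P)

    @property
    def global_token(self) -> Tensor:
        return self.tokens[:, 0, :]

    @property
    def patch_tokens(self) -> Tensor:
        return self.tokens[:, 1:, :]

    def attention_tensor(self, sample: int = 0) -> np.ndarray:
        """Stacked attention maps for one sample: (depth, heads, 1+P, 1+P)."""
        if not self.attentions:
            raise ValueError("attention maps were not stored; pass store_attention=True")
        return np.stack([a[sample] for a in self.attentions], axis=0)


@dataclass
class FeaturePyramid:
    """FPN levels at strides 4, 8 and 32 with a common channel width."""

    p2: Tensor
    p3: Tensor
    p5: Tensor

    @property
    def channels(self) -> int:
        return self.p2.shape[1]


@dataclass
class FusedFeatureMap:
    values: Tensor
    fusion_method: str = "addition"

    @property
    def channels(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# patch embedding
# ---------------------------------------------------------------------------

def patchify(img, patch_size: int):
    """Split an (N, C, H, W) raster into flattened non-overlapping patches.

    Returns (N, (H/p)*(W/p), C*p*p) in row-major grid order. Each token is
    the patch flattened channel-first.
    """
    data = img if isinstance(img, Tensor) else Tensor(np.asarray(img, np.float32))
    n, c, h, w = data.shape
    p = patch_size
    if h % p or w % p:
        raise ValueError(f"image size {h}x{w} not divisible by patch size {p}")
    gh, gw = h // p, w // p
    x = data.reshape(n, c, gh, p, gw, p)
    x = x.transpose(0, 2, 4, 1, 3, 5)  # n, gh, gw, c, p, p
    return x.reshape(n, gh * gw, c * p * p)


def unpatchify(tokens, grid: tuple[int, int], patch_size: int, channels: int = 3):
    """Inverse of :func:`patchify`."""
    data = tokens if isinstance(tokens, Tensor) else Tensor(np.asarray(tokens, np.float32))
    n = data.shape[0]
    gh, gw = grid
    p = patch_size
    x = data.reshape(n, gh, gw, channels, p, p)
    x = x.transpose(0, 3, 1, 4, 2, 5)
    return x.reshape(n, channels, gh * p, gw * p)


# ---------------------------------------------------------------------------
# GFE: vision transformer
# ---------------------------------------------------------------------------

class MultiHeadSelfAttention(nn.Module):
    def __init__(self, dim: int, num_heads: int, rng: np.random.Generator):
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.scale = self.head_dim ** -0.5
        self.qkv = nn.Linear(dim, dim * 3, rng, std=0.02)
        self.proj = nn.Linear(dim, dim, rng, std=0.02)

    def forward(self, x: Tensor, store_attention: bool = False):
        n, t, d = x.shape
        h, hd = self.num_heads, self.head_dim
        qkv = self.qkv(x).reshape(n, t, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (n, h, t, hd)
        attn = nn.softmax((q @ k.transpose(0, 1, 3, 2)) * self.scale, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        attn_np = np.ascontiguousarray(attn.data) if store_attention else None
        return self.proj(out), attn_np


class TransformerBlock(nn.Module):
    def __init__(self, dim: int, num_heads: int, mlp_ratio: int, rng: np.random.Generator):
        self.norm1 = nn.LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, num_heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, dim * mlp_ratio, rng, std=0.02)
        self.fc2 = nn.Linear(dim * mlp_ratio, dim, rng, std=0.02)

    def forward(self, x: Tensor, store_attention: bool = False):
        y, attn = self.attn(self.norm1(x), store_attention)
        x = x + y
        x = x + self.fc2(self.fc1(self.norm2(x)).gelu())
        return x, attn


class ViTEncoder(nn.Module):
    """Standard ViT encoder: patch embedding, learned position embedding,
    prepended global token, pre-norm transformer blocks, final layer norm."""

    def __init__(self, cfg: ViTConfig, rng: np.random.Generator, in_channels: int = 3):
        self.cfg = cfg
        g = cfg.input_size // cfg.patch_size
        self.grid = (g, g)
        patch_dim = in_channels * cfg.patch_size ** 2
        self.patch_embed = nn.Linear(patch_dim, cfg.embed_dim, rng, std=0.02)
        self.cls_token = nn.Parameter(trunc(rng, (1, 1, cfg.embed_dim)))
        self.pos_embed = nn.Parameter(trunc(rng, (1, 1 + g * g, cfg.embed_dim)))
        self.blocks = nn.ModuleList(
            [TransformerBlock(cfg.embed_dim, cfg.num_heads, cfg.mlp_ratio, rng) for _ in range(cfg.depth)]
        )
        self.norm = nn.LayerNorm(cfg.embed_dim)

    def _positional(self, grid: tuple[int, int]) -> Tensor:
        """Position embeddings, bilinearly interpolated for off-size grids."""
        g0 = self.grid
        if grid == g0:
            return self.pos_embed
        d = self.cfg.embed_dim
        cls = self.pos_embed[:, :1, :]
        patch = self.pos_embed[:, 1:, :].reshape(1, g0[0], g0[1], d).transpose(0, 3, 1, 2)
        patch = nn.bilinear_resize(patch, grid[0], grid[1])
        patch = patch.transpose(0, 2, 3, 1).reshape(1, grid[0] * grid[1], d)
        return nn.cat([cls, patch], axis=1)

    def forward(self, img, store_attention: bool = False) -> TokenEmbeddings:
        data = img if isinstance(img, Tensor) else Tensor(np.asarray(img, np.float32))
        n, c, h, w = data.shape
        p = self.cfg.patch_size
        grid = (h // p, w // p)
        tok = self.patch_embed(patchify(data, p))
        cls = nn.cat([self.cls_token] * n, axis=0) if n > 1 else self.cls_token
        x = nn.cat([cls, tok], axis=1) + self._positional(grid)
        attentions = []
        for blk in self.blocks:
            x, attn = blk(x, store_attention)
            if store_attention:
                attentions.append(attn)
        x = self.norm(x)
        return TokenEmbeddings(tokens=x, grid=grid, attentions=attentions)


def trunc(rng, shape, std=0.02):
    return nn.trunc_normal(rng, shape, std)


class ProjectionHead(nn.Module):
    """3-layer perceptron head applied to the global token for the SSL objective."""

    def __init__(self, in_dim: int, rng: np.random.Generator,
                 hidden_dim: int = 2048, out_dim: int = 256):
        self.fc1 = nn.Linear(in_dim, hidden_dim, rng)
        self.fc2 = nn.Linear(hidden_dim, hidden_dim, rng)
        self.fc3 = nn.Linear(hidden_dim, out_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc3(self.fc2(self.fc1(x).gelu()).gelu())


# ---------------------------------------------------------------------------
# FFE: ResNet + FPN
# ---------------------------------------------------------------------------

class BasicBlock(nn.Module):
    expansion = 1

    def __init__(self, in_ch: int, ch: int, stride: int, rng):
        self.conv1 = nn.Conv2d(in_ch, ch, 3, rng, stride=stride, pad=1, bias=False)
        self.n1 = nn.GroupNorm(ch)
        self.conv2 = nn.Conv2d(ch, ch, 3, rng, pad=1, bias=False)
        self.n2 = nn.GroupNorm(ch)
        if stride != 1 or in_ch != ch:
            self.short = nn.Conv2d(in_ch, ch, 1, rng, stride=stride, bias=False)
        else:
            self.short = nn.Identity()

    def forward(self, x):
        y = self.n1(self.conv1(x)).relu()
        y = self.n2(self.conv2(y))
        return (y + self.short(x)).relu()


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_ch: int, ch: int, stride: int, rng):
        out = ch * self.expansion
        self.conv1 = nn.Conv2d(in_ch, ch, 1, rng, bias=False)
        self.n1 = nn.GroupNorm(ch)
        self.conv2 = nn.Conv2d(ch, ch, 3, rng, stride=stride, pad=1, bias=False)
        self.n2 = nn.GroupNorm(ch)
        self.conv3 = nn.Conv2d(ch, out, 1, rng, bias=False)
        self.n3 = nn.GroupNorm(out)
        if stride != 1 or in_ch != out:
            self.short = nn.Conv2d(in_ch, out, 1, rng, stride=stride, bias=False)
        else:
            self.short = nn.Identity()

    def forward(self, x):
        y = self.n1(self.conv1(x)).relu()
        y = self.n2(self.conv2(y)).relu()
        y = self.n3(self.conv3(y))
        return (y + self.short(x)).relu()


RESNET_LAYOUTS = {
    "resnet18": (BasicBlock, (2, 2, 2, 2)),
    "resnet50": (Bottleneck, (3, 4, 6, 3)),
}


class ResNetFPN(nn.Module):
    """ResNet stages C2–C5 with a top-down FPN emitting P2, P3 and P5.

    ``base_width`` scales every stage width (64 reproduces the standard
    ResNet); ``fpn_channels`` is the common pyramid width. Normalization is
    GroupNorm so outputs are independent of batch composition.
    """

    def __init__(self, backbone: str, rng: np.random.Generator,
                 base_width: int = 64, fpn_channels: int = 256, in_channels: int = 3):
        if backbone not in RESNET_LAYOUTS:
            raise ValueError(f"unknown backbone {backbone!r}; expected one of {sorted(RESNET_LAYOUTS)}")
        block, counts = RESNET_LAYOUTS[backbone]
        w = base_width
        self.conv1 = nn.Conv2d(in_channels, w, 7, rng, stride=2, pad=3, bias=False)
        self.n1 = nn.GroupNorm(w)
        widths = (w, 2 * w, 4 * w, 8 * w)
        strides = (1, 2, 2, 2)
        in_ch = w
        self.stages = nn.ModuleList()
        self.out_channels = []
        for width, count, stride in zip(widths, counts, strides):
            blocks = []
            for i in range(count):
                blocks.append(block(in_ch, width, stride if i == 0 else 1, rng))
                in_ch = width * block.expansion
            self.stages.append(nn.Sequential(*blocks))
            self.out_channels.append(in_ch)
        self.fpn_channels = fpn_channels
        self.laterals = nn.ModuleList(
            [nn.Conv2d(c, fpn_channels, 1, rng) for c in self.out_channels]
        )
        self.smooth = nn.ModuleList(
            [nn.Conv2d(fpn_channels, fpn_channels, 3, rng, pad=1) for _ in range(3)]
        )

    def forward(self, img) -> FeaturePyramid:
        x = img if isinstance(img, Tensor) else Tensor(np.asarray(img, np.float32))
        n, c, h, w = x.shape
        if h % 32 or w % 32:
            raise ValueError(f"input spatial size {h}x{w} must be divisible by 32")
        x = self.n1(self.conv1(x)).relu()
        x = nn.max_pool2d(x, 3, 2, 1)
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        c2, c3, c4, c5 = feats
        l2, l3, l4, l5 = (lat(f) for lat, f in zip(self.laterals, feats))
        t5 = l5
        t4 = l4 + nn.upsample_nearest2x(t5)
        t3 = l3 + nn.upsample_nearest2x(t4)
        t2 = l2 + nn.upsample_nearest2x(t3)
        return FeaturePyramid(
            p2=self.smooth[0](t2), p3=self.smooth[1](t3), p5=self.smooth[2](t5)
        )


def upsample_to_p2(pyr: FeaturePyramid) -> tuple[Tensor, Tensor, Tensor]:
    """Bilinearly resize P3 and P5 to the P2 resolution; P2 passes through."""
    h, w = pyr.p2.shape[2], pyr.p2.shape[3]
    return pyr.p2, nn.bilinear_resize(pyr.p3, h, w), nn.bilinear_resize(pyr.p5, h, w)


# ---------------------------------------------------------------------------
# multi-scale fusion
# ---------------------------------------------------------------------------

class MultiScaleFusion(nn.Module):
    """Combine the FFE stack with the projected GFE patch-token grid.

    The three P2-resolution FFE maps are concatenated (3*C_fpn channels);
    the GFE patch tokens are reshaped to their grid, projected with a 1x1
    linear map to 3*C_fpn channels and bilinearly resized to the P2 grid;
    the stacks are combined element-wise (addition/multiplication) or by
    channel concatenation.
    """

    def __init__(self, embed_dim: int, fpn_channels: int, rng: np.random.Generator,
                 method: str = "addition"):
        if method not in FUSION_METHODS:
            raise ValueError(f"unknown fusion method {method!r}; expected one of {FUSION_METHODS}")
        self.method = method
        self.fpn_channels = fpn_channels
        self.proj = nn.Linear(embed_dim, 3 * fpn_channels, rng)

    def gfe_grid_map(self, gfe: TokenEmbeddings, out_hw: tuple[int, int]) -> Tensor:
        gh, gw = gfe.grid
        n = gfe.tokens.shape[0]
        patches = self.proj(gfe.patch_tokens)  # (n, gh*gw, 3C)
        grid = patches.reshape(n, gh, gw, 3 * self.fpn_channels).transpose(0, 3, 1, 2)
        return nn.bilinear_resize(grid, out_hw[0], out_hw[1])

    def forward(self, pyr: FeaturePyramid, gfe: TokenEmbeddings,
                method: str | None = None) -> FusedFeatureMap:
        method = method or self.method
        p2, p3u, p5u = upsample_to_p2(pyr)
        ffe_stack = nn.cat([p2, p3u, p5u], axis=1)
        gfe_map = self.gfe_grid_map(gfe, (p2.shape[2], p2.shape[3]))
        values = fuse_stacks(ffe_stack, gfe_map, method)
        return FusedFeatureMap(values=values, fusion_method=method)


def fuse_stacks(ffe_stack: Tensor, gfe_map: Tensor, method: str) -> Tensor:
    """Element-wise addition/multiplication or channel concatenation of two
    equally-shaped feature stacks."""
    if method == "addition":
        return ffe_stack + gfe_map
    if method == "multiplication":
        return ffe_stack * gfe_map
    if method == "concatenation":
        return nn.cat([ffe_stack, gfe_map], axis=1)
    raise ValueError(f"unknown fusion method {method!r}; expected one of {FUSION_METHODS}")
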