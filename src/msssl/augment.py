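"""SimCLR-style stochastic two-view augmentation.

Each view independently applies, in order: random resized crop, horizontal
flip, color jitter (brightness/contrast/saturation/hue), Gaussian blur with a
kernel drawn from a configured set, and per-channel standardization. When a
binary mask accompanies the image, the geometric operations (crop, flip) are
replayed on the mask with the exact parameters sampled for the view, while
photometric operations skip it — so mask and view stay aligned.

All randomness flows through an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

from .nn.tensor import _bilinear_coeffs


@dataclass
class AugmentConfig:
    crop_size: int = 224
    flip_prob: float = 0.5
    brightness: float = 0.4
    contrast: float = 0.4
    saturation: float = 0.4
    hue: float = 0.1
    blur_kernels: tuple = (3, 5, 7)
    blur_prob: float = 0.5
    crop_scale: tuple = (0.3, 1.0)
    crop_ratio: tuple = (3.0 / 4.0, 4.0 / 3.0)
    mean: tuple = (0.5, 0.5, 0.5)
    std: tuple = (0.5, 0.5, 0.5)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        if self.crop_size < 32:
            raise ValueError("crop_size must be >= 32")
        for k in self.blur_kernels:
            if k < 3 or k % 2 == 0:
                raise ValueError(f"blur kernels must be odd and >= 3, got {k}")


@dataclass
class AugmentedViewPair:
    view_a: np.ndarray  # (3, crop_size, crop_size) float32
    view_b: np.ndarray
    source_id: str = ""
    mask_a: np.ndarray | None = None  # (crop_size, crop_size) uint8
    mask_b: np.ndarray | None = None


def _resize_bilinear_chw(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    c, h, w = img.shape
    if (h, w) == (out_h, out_w):
        return img.copy()
    i0, i1, fi = _bilinear_coeffs(h, out_h)
    j0, j1, fj = _bilinear_coeffs(w, out_w)
    wi = fi[None, :, None]
    wj = fj[None, None, :]
    top = (1 - wj) * img[:, i0][:, :, j0] + wj * img[:, i0][:, :, j1]
    bot = (1 - wj) * img[:, i1][:, :, j0] + wj * img[:, i1][:, :, j1]
    return ((1 - wi) * top + wi * bot).astype(np.float32)


def _resize_nearest_hw(mask: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = mask.shape
    if (h, w) == (out_h, out_w):
        return mask.copy()
    i0, i1, fi = _bilinear_coeffs(h, out_h)
    j0, j1, fj = _bilinear_coeffs(w, out_w)
    ri = np.where(fi < 0.5, i0, i1)
    rj = np.where(fj < 0.5, j0, j1)
    return mask[ri][:, rj]


def _sample_crop_box(rng: np.random.Generator, h: int, w: int, scale, ratio):
    """torchvision-style RandomResizedCrop box sampling (10 attempts, then
    a centered fallback). scale == (1, 1) with ratio (1, 1) is the full box."""
    if scale == (1.0, 1.0) and tuple(ratio) == (1.0, 1.0):
        return 0, 0, h, w
    area = h * w
    log_ratio = (np.log(ratio[0]), np.log(ratio[1]))
    for _ in range(10):
        target = area * rng.uniform(scale[0], scale[1])
        ar = np.exp(rng.uniform(*log_ratio))
        cw = int(round(np.sqrt(target * ar)))
        ch = int(round(np.sqrt(target / ar)))
        if 0 < cw <= w and 0 < ch <= h:
            top = int(rng.integers(0, h - ch + 1))
            left = int(rng.integers(0, w - cw + 1))
            return top, left, ch, cw
    side = min(h, w)
    return (h - side) // 2, (w - side) // 2, side, side


def _color_jitter(img: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig) -> np.ndarray:
    out = img
    if cfg.brightness > 0:
        out = out * rng.uniform(max(0.0, 1 - cfg.brightness), 1 + cfg.brightness)
    if cfg.contrast > 0:
        f = rng.uniform(max(0.0, 1 - cfg.contrast), 1 + cfg.contrast)
        gray = out.mean()
        out = (out - gray) * f + gray
    if cfg.saturation > 0:
        f = rng.uniform(max(0.0, 1 - cfg.saturation), 1 + cfg.saturation)
        gray = out.mean(axis=0, keepdims=True)
        out = (out - gray) * f + gray
    out = np.clip(out, 0.0, 1.0)
    if cfg.hue > 0:
        shift = rng.uniform(-cfg.hue, cfg.hue)
        hsv = skcolor.rgb2hsv(out.transpose(1, 2, 0))
        hsv[:, :, 0] = (hsv[:, :, 0] + shift) % 1.0
        out = skcolor.hsv2rgb(hsv).transpose(2, 0, 1).astype(np.float32)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _augment_one(img: np.ndarray, mask: np.ndarray | None,
                 cfg: AugmentConfig, rng: np.random.Generator):
    c, h, w = img.shape
    top, left, ch, cw = _sample_crop_box(rng, h, w, tuple(cfg.crop_scale), tuple(cfg.crop_ratio))
    view = _resize_bilinear_chw(img[:, top:top + ch, left:left + cw], cfg.crop_size, cfg.crop_size)
    m = None
    if mask is not None:
        m = _resize_nearest_hw(mask[top:top + ch, left:left + cw], cfg.crop_size, cfg.crop_size)
    if rng.uniform() < cfg.flip_prob:
        view = view[:, :, ::-1].copy()
        if m is not None:
            m = m[:, ::-1].copy()
    view = _color_jitter(view, rng, cfg)
    if cfg.blur_kernels and rng.uniform() < cfg.blur_prob:
        k = int(rng.choice(cfg.blur_kernels))
        sigma = 0.3 * ((k - 1) * 0.5 - 1) + 0.8
        view = np.stack([
            ndimage.gaussian_filter(view[i], sigma=sigma, radius=k // 2) for i in range(c)
        ]).astype(np.float32)
    mean = np.asarray(cfg.mean, np.float32)[:, None, None]
    std = np.asarray(cfg.std, np.float32)[:, None, None]
    view = (view - mean) / std
    return view.astype(np.float32), m


def make_view_pair(img: np.ndarray, mask: np.ndarray | None,
                   cfg: AugmentConfig, rng_state, source_id: str = "",
                   img_b: np.ndarray | None = None,
                   mask_b: np.ndarray | None = None) -> AugmentedViewPair:
    """Two independently augmented views of one image (optionally of a
    left/right dual-view pair when ``img_b`` is given).

    ``img`` is a (3, H, W) float raster in [0, 1]; standardization with the
    configured mean/std is the pipeline's last step. Deterministic given
    ``rng_state``.
    """
    rng = rng_state if isinstance(rng_state, np.random.Generator) else np.random.default_rng(rng_state)
    img = np.asarray(img, np.float32)
    if img.ndim != 3 or img.shape[0] != 3:
        raise ValueError(f"expected a (3, H, W) raster, got shape {img.shape}")
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != img.shape[1:]:
            raise ValueError(f"mask shape {mask.shape} does not match image {img.shape[1:]}")
    second = img if img_b is None else np.asarray(img_b, np.float32)
    second_mask = mask if img_b is None else mask_b
    if second_mask is not None:
        second_mask = np.asarray(second_mask)
        if second_mask.shape != second.shape[1:]:
            raise ValueError("mask shape does not match image")
    va, ma = _augment_one(img, mask, cfg, rng)
    vb, mb = _augment_one(second, second_mask, cfg, rng)
    return AugmentedViewPair(view_a=va, view_b=vb, source_id=source_id, mask_a=ma, mask_b=mb)
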