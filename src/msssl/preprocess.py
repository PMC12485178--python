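"""Fundus preprocessing: green channel, border cropping, saliency, masks.

The green plane of an RGB fundus photograph carries the highest
lesion/vessel contrast, so the whole pipeline operates on it. A saliency
detector applied to the green channel produces per-pixel conspicuity in
[0, 1]; Otsu thresholding turns the map into the binary mask that serves as
ground truth for the self-supervised segmentation objective.

Two detectors are provided:

* ``spectral_saliency`` — the spectral-residual method: the log-amplitude
  spectrum minus its 3x3 mean-filtered version is the residual; the inverse
  transform of residual + phase, squared and Gaussian-smoothed, is the map.
* ``fine_grained_saliency`` — multi-radius center–surround contrast: the
  absolute difference between each pixel and its box-filtered surround,
  summed over window radii (default 3, 7, 15).

Both min-max normalize to [0, 1]; a constant input yields an all-zero map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .synthetic import FundusImage

SALIENCY_METHODS = ("spectral", "fine_grained")


@dataclass
class GreenChannelImage:
    pixels: np.ndarray  # (H, W) uint8
    id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"green-channel image must be 2-D, got shape {self.pixels.shape}")


@dataclass
class SaliencyMap:
    values: np.ndarray  # (H, W) float in [0, 1]
    method: str

    def __post_init__(self):
        self.values = np.asarray(self.values, np.float64)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("saliency values must lie in [0, 1]")
        if self.method not in SALIENCY_METHODS:
            raise ValueError(f"method must be one of {SALIENCY_METHODS}")

    def save(self, path) -> None:
        Image.fromarray((self.values * 255).round().astype(np.uint8)).save(path)


@dataclass
class BinaryMask:
    values: np.ndarray  # (H, W) in {0, 1}

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.values = self.values.astype(np.uint8)

    def save(self, path) -> None:
        Image.fromarray(self.values * 255).save(path)


def _as_rgb(img) -> np.ndarray:
    arr = img.pixels if isinstance(img, FundusImage) else np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {arr.shape}")
    return arr


def _as_plane(img) -> np.ndarray:
    if isinstance(img, GreenChannelImage):
        return np.asarray(img.pixels, np.float64)
    arr = np.asarray(img, np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got shape {arr.shape}")
    return arr


def extract_green_channel(img) -> GreenChannelImage:
    """Take the G plane (index 1 in R,G,B order) of an RGB image."""
    arr = _as_rgb(img)
    ident = img.id if isinstance(img, FundusImage) else ""
    return GreenChannelImage(pixels=arr[:, :, 1].copy(), id=ident)


def crop_black_borders(img, intensity_threshold: int = 10):
    """Tight bounding-box crop of pixels whose max channel exceeds the threshold."""
    if not 0 <= intensity_threshold <= 255:
        raise ValueError("intensity_threshold must be in [0, 255]")
    arr = _as_rgb(img)
    fg = arr.max(axis=2) > intensity_threshold
    if not fg.any():
        raise ValueError("empty foreground: no pixel above threshold")
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    cropped = arr[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    if isinstance(img, FundusImage):
        return FundusImage(pixels=cropped.copy(), id=img.id, grade=img.grade,
                           view=img.view, n_lesions=img.n_lesions)
    return cropped.copy()


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo < 1e-12:  # constant map guard
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def spectral_saliency(img) -> SaliencyMap:
    """Spectral-residual saliency of a single-channel image."""
    plane = _as_plane(img)
    if plane.size == 0:
        raise ValueError("empty image")
    if plane.max() - plane.min() < 1e-9:  # constant image: nothing is salient
        return SaliencyMap(values=np.zeros_like(plane), method="spectral")
    spectrum = np.fft.fft2(plane)
    amplitude = np.abs(spectrum)
    phase = np.angle(spectrum)
    log_amp = np.log(amplitude + 1e-12)
    residual = log_amp - ndimage.uniform_filter(log_amp, size=3, mode="nearest")
    recon = np.fft.ifft2(np.exp(residual + 1j * phase))
    sal = np.abs(recon) ** 2
    sal = ndimage.gaussian_filter(sal, sigma=2.5)
    return SaliencyMap(values=_minmax(sal), method="spectral")


def fine_grained_saliency(img, radii=(3, 7, 15)) -> SaliencyMap:
    """Multi-radius center–surround box-filter contrast saliency."""
    plane = _as_plane(img)
    if plane.size == 0:
        raise ValueError("empty image")
    sal = np.zeros_like(plane)
    for r in radii:
        surround = ndimage.uniform_filter(plane, size=2 * r + 1, mode="nearest")
        sal += np.abs(plane - surround)
    return SaliencyMap(values=_minmax(sal), method="fine_grained")


def compute_saliency(img, method: str = "fine_grained") -> SaliencyMap:
    if method == "spectral":
        return spectral_saliency(img)
    if method == "fine_grained":
        return fine_grained_saliency(img)
    raise ValueError(f"unknown saliency method {method!r}; expected one of {SALIENCY_METHODS}")


def otsu_threshold_bin(values: np.ndarray) -> int | None:
    """Otsu's threshold over the 256-bin histogram of a [0,1] map.

    Returns the cut bin t (mask = quantized value >= t), or None for a
    constant map.
    """
    q = np.clip((np.asarray(values, np.float64) * 255.0).astype(np.int64), 0, 255)
    hist = np.bincount(q.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    bins = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)[:-1]                 # weight of class {bin < t} for t = 1..255
    w1 = total - w0
    s0 = np.cumsum(hist * bins)[:-1]
    mu_total = (hist * bins).sum()
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return None
    mu0 = np.where(w0 > 0, s0 / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (mu_total - s0) / np.maximum(w1, 1), 0.0)
    var_between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return int(np.argmax(var_between)) + 1    # first maximizer, lowest cut


def binarize_saliency(saliency: SaliencyMap | np.ndarray) -> BinaryMask:
    """Threshold a saliency map with Otsu's rule; constant maps give an
    all-zero mask."""
    values = saliency.values if isinstance(saliency, SaliencyMap) else np.asarray(saliency)
    t = otsu_threshold_bin(values)
    if t is None:
        return BinaryMask(values=np.zeros(values.shape, np.uint8))
    q = np.clip((values * 255.0).astype(np.int64), 0, 255)
    return BinaryMask(values=(q >= t).astype(np.uint8))


def normalize_for_model(img, mean: float = 0.5, std: float = 0.5) -> np.ndarray:
    """Green plane replicated to 3 channels, scaled to [0,1], standardized.

    Returns a float32 (3, H, W) raster ready for the encoders.
    """
    plane = _as_plane(img) / 255.0
    out = (plane - mean) / std
    return np.repeat(out[None, :, :], 3, axis=0).astype(np.float32)


def green_unit_raster(img) -> np.ndarray:
    """Green plane replicated to 3 channels in [0,1] (pre-standardization),
    the form the augmentation pipeline consumes."""
    plane = _as_plane(img) / 255.0
    return np.repeat(plane[None, :, :], 3, axis=0).astype(np.float32)
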