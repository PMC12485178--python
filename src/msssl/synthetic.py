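"""Synthetic fundus-photograph generator.

Emulates the gross structure of color fundus photographs so the whole
pipeline is exercisable without clinical data: a bright, green-dominant
circular retina on a black frame, one elliptical optic-disc highlight, a
dark random-walk vessel tree, and grade-dependent lesions. Lesion counts are
Poisson with a per-grade expected rate that must increase strictly with
grade, so an ordinal signal exists by construction; each lesion is a small
dark dot (hemorrhage-like) or a small bright blob (exudate-like) with equal
probability. Dual-view mode renders a left/right pair of the same synthetic
eye: the lesion layout is shared up to horizontal mirroring while the vessel
noise is drawn independently per view.

No photorealism is attempted; the generator's purpose is a controllable,
deterministic effect size, not clinical plausibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

VIEWS = ("single", "left", "right")

DEFAULT_RATES = (0.0, 2.0, 5.0, 10.0, 20.0)


@dataclass
class SyntheticConfig:
    image_size: int = 224
    retina_radius_frac: float = 0.92
    lesion_rate_per_grade: tuple = DEFAULT_RATES
    dual_view: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError(f"image_size must be >= 64, got {self.image_size}")
        if not 0.0 < self.retina_radius_frac <= 1.0:
            raise ValueError("retina_radius_frac must be in (0, 1]")
        rates = tuple(float(r) for r in self.lesion_rate_per_grade)
        if len(rates) != 5:
            raise ValueError("lesion_rate_per_grade must have 5 entries (grades 0..4)")
        if any(r < 0 for r in rates):
            raise ValueError("lesion rates must be non-negative")
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValueError("lesion_rate_per_grade must be strictly increasing in grade")
        self.lesion_rate_per_grade = rates

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class FundusImage:
    """8-bit RGB raster with identity, optional ordinal grade, and view tag."""

    pixels: np.ndarray  # (H, W, 3) uint8
    id: str
    grade: int | None = None
    view: str = "single"
    n_lesions: int | None = None  # generator-side tally, handy for validation

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.grade is not None and self.grade not in (0, 1, 2, 3, 4):
            raise ValueError(f"grade must be in 0..4, got {self.grade}")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}")

    def save(self, path) -> None:
        Image.fromarray(self.pixels).save(path)

    @classmethod
    def load(cls, path, id: str | None = None, grade: int | None = None,
             view: str = "single") -> "FundusImage":
        arr = np.asarray(Image.open(path).convert("RGB"))
        return cls(pixels=arr, id=id or Path(path).stem, grade=grade, view=view)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_RETINA_RGB = np.array([95.0, 170.0, 55.0])
_DISC_RGB = np.array([215.0, 235.0, 175.0])
_VESSEL_RGB = np.array([40.0, 75.0, 30.0])
_DARK_LESION_RGB = np.array([25.0, 50.0, 20.0])
_BRIGHT_LESION_RGB = np.array([225.0, 240.0, 185.0])


def _paint(canvas: np.ndarray, alpha: np.ndarray, rgb: np.ndarray) -> None:
    a = alpha[..., None]
    canvas *= 1.0 - a
    canvas += a * rgb


def _stamp_disc(alpha: np.ndarray, cy: float, cx: float, radius: float) -> None:
    """max-composite a soft disc into ``alpha`` touching only a local window."""
    size = alpha.shape[0]
    r = int(np.ceil(radius + 1))
    y0, y1 = max(0, int(cy) - r), min(size, int(cy) + r + 2)
    x0, x1 = max(0, int(cx) - r), min(size, int(cx) + r + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    d = np.hypot(yy - cy, xx - cx)
    np.maximum(alpha[y0:y1, x0:x1], np.clip(radius - d, 0.0, 1.0), out=alpha[y0:y1, x0:x1])


def _sample_in_disc(rng: np.random.Generator, cy, cx, radius, margin=0.12):
    r = radius * (1.0 - margin) * np.sqrt(rng.uniform())
    t = rng.uniform(0, 2 * np.pi)
    return cy + r * np.sin(t), cx + r * np.cos(t)


def _draw_vessels(canvas, rng, cy, cx, oy, ox, radius, n_branches):
    size = canvas.shape[0]
    alpha = np.zeros((size, size))
    for _ in range(n_branches):
        y, x = oy, ox
        theta = rng.uniform(0, 2 * np.pi)
        n_steps = int(radius * 1.6)
        for _ in range(n_steps):
            theta += rng.normal(0.0, 0.28)
            y += np.sin(theta)
            x += np.cos(theta)
            if np.hypot(y - cy, x - cx) > radius * 0.95:
                break
            _stamp_disc(alpha, y, x, 1.3)
    _paint(canvas, alpha * 0.85, _VESSEL_RGB)


def _render_view(cfg: SyntheticConfig, grade: int, rng: np.random.Generator,
                 lesions: list, mirror: bool, image_id: str, view: str) -> FundusImage:
    s = cfg.image_size
    c = (s - 1) / 2.0
    radius = cfg.retina_radius_frac * s / 2.0
    canvas = np.zeros((s, s, 3))

    # retina base with a gentle radial falloff and pixel noise
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    d = np.hypot(yy - c, xx - c)
    shade = 1.0 - 0.25 * np.clip(d / radius, 0.0, 1.0) ** 2
    canvas[:] = _RETINA_RGB * shade[..., None]
    canvas += rng.normal(0.0, 4.0, canvas.shape)

    # optic disc: elliptical highlight off-center along the horizontal axis
    side = -1.0 if mirror else 1.0
    oy = c + rng.normal(0.0, 0.05) * radius
    ox = c + side * 0.45 * radius
    ang = rng.uniform(-0.3, 0.3)
    ca, sa = np.cos(ang), np.sin(ang)
    u = (xx - ox) * ca + (yy - oy) * sa
    v = -(xx - ox) * sa + (yy - oy) * ca
    ell = (u / (0.16 * radius)) ** 2 + (v / (0.12 * radius)) ** 2
    _paint(canvas, np.clip(1.5 - ell, 0.0, 1.0).clip(0, 1) * 0.9, _DISC_RGB)

    # vessel tree rooted at the optic disc (independent noise per view)
    _draw_vessels(canvas, rng, c, c, oy, ox, radius, n_branches=rng.integers(4, 8))

    # grade-dependent lesions (shared layout across views, mirrored)
    for (ly, lx, lr, bright) in lesions:
        px = (s - 1) - lx if mirror else lx
        alpha = np.zeros((s, s))
        _stamp_disc(alpha, ly, px, lr)
        _paint(canvas, alpha, _BRIGHT_LESION_RGB if bright else _DARK_LESION_RGB)

    # hard black frame outside the retina (soft edge <= 2 px)
    edge = np.clip(radius - d, 0.0, 1.0)
    canvas *= edge[..., None]
    pixels = np.clip(canvas, 0, 255).astype(np.uint8)
    return FundusImage(pixels=pixels, id=image_id, grade=grade, view=view,
                       n_lesions=len(lesions))


def _draw_lesions(cfg: SyntheticConfig, grade: int, rng: np.random.Generator) -> list:
    s = cfg.image_size
    c = (s - 1) / 2.0
    radius = cfg.retina_radius_frac * s / 2.0
    n = int(rng.poisson(cfg.lesion_rate_per_grade[grade]))
    lesions = []
    for _ in range(n):
        ly, lx = _sample_in_disc(rng, c, c, radius)
        bright = rng.uniform() < 0.5
        lr = rng.uniform(1.5, 3.5) if bright else rng.uniform(1.0, 2.5)
        lesions.append((ly, lx, lr, bright))
    return lesions


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def generate_fundus(cfg: SyntheticConfig, grade: int, rng_state,
                    image_id: str | None = None, view: str = "single") -> FundusImage:
    """Render one synthetic fundus image of the given grade.

    Deterministic given ``rng_state`` (a seed or a ``numpy.random.Generator``).
    """
    if grade not in (0, 1, 2, 3, 4):
        raise ValueError(f"grade must be in 0..4, got {grade}")
    rng = _as_rng(rng_state)
    lesions = _draw_lesions(cfg, grade, rng)
    return _render_view(cfg, grade, rng, lesions, mirror=(view == "right"),
                        image_id=image_id or f"synthetic_g{grade}", view=view)


def generate_eye_pair(cfg: SyntheticConfig, grade: int, rng_state,
                      image_id: str) -> tuple[FundusImage, FundusImage]:
    """Left/right views of one synthetic eye: shared lesion layout up to
    mirroring, independent vessel noise."""
    rng = _as_rng(rng_state)
    lesions = _draw_lesions(cfg, grade, rng)
    left = _render_view(cfg, grade, rng, lesions, mirror=False, image_id=image_id, view="left")
    right = _render_view(cfg, grade, rng, lesions, mirror=True, image_id=image_id, view="right")
    return left, right


def generate_dataset(cfg: SyntheticConfig, n_per_grade: int,
                     out_dir=None) -> tuple[list[FundusImage], pd.DataFrame]:
    """Generate ``5 * n_per_grade`` labeled images (doubled when dual-view).

    Returns the images plus a manifest with columns ``id, grade, view``.
    When ``out_dir`` is given, PNGs and ``manifest.csv`` are written there.
    """
    if n_per_grade < 1:
        raise ValueError("n_per_grade must be >= 1")
    rng = cfg.rng()
    images: list[FundusImage] = []
    rows = []
    for grade in range(5):
        for i in range(n_per_grade):
            image_id = f"g{grade}_{i:04d}"
            if cfg.dual_view:
                left, right = generate_eye_pair(cfg, grade, rng, image_id)
                images += [left, right]
                rows.append({"id": image_id, "grade": grade, "view": "left"})
                rows.append({"id": image_id, "grade": grade, "view": "right"})
            else:
                images.append(generate_fundus(cfg, grade, rng, image_id=image_id))
                rows.append({"id": image_id, "grade": grade, "view": "single"})
    manifest = pd.DataFrame(rows, columns=["id", "grade", "view"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img in images:
            suffix = "" if img.view == "single" else f"_{img.view}"
            img.save(out / f"{img.id}{suffix}.png")
        manifest.to_csv(out / "manifest.csv", index=False)
    return images, manifest


def retina_mask(cfg_or_image, image_size: int | None = None,
                retina_radius_frac: float | None = None) -> np.ndarray:
    """Boolean mask of the retina disc interior (excluding the soft edge)."""
    if isinstance(cfg_or_image, SyntheticConfig):
        s = cfg_or_image.image_size
        frac = cfg_or_image.retina_radius_frac
    else:
        s = image_size
        frac = retina_radius_frac
    c = (s - 1) / 2.0
    radius = frac * s / 2.0
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    return np.hypot(yy - c, xx - c) <= radius - 2.0
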