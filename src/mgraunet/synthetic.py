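"""Synthetic low-contrast lesion generator.

Produces endoscopy-like image/mask pairs without any downloads: a
tissue-toned background with smooth low-frequency texture, plus one or
more deformed-ellipse lesions whose mean intensity differs from the
background by a configurable (deliberately small) offset.  Lesion
boundaries are perturbed by low-order radial harmonics so shapes are
irregular, and the image-side lesion edge is feathered while the mask
remains the exact pixel support of the lesion.  Generation is bitwise
deterministic for a fixed seed.

These images emulate the statistical difficulties of polyp data —
low lesion/background contrast, varied morphology, ambiguous
boundaries — not its optics (no specular highlights, vignetting,
instruments or depth effects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data import SegmentationSample

_BASE_TONE = np.array([168.0, 104.0, 92.0])  # mucosa-like RGB


@dataclass
class SynthConfig:
    n_images: int = 200
    image_size: int = 64
    lesions_per_image: tuple[int, int] = (1, 2)
    lesion_area_fraction: tuple[float, float] = (0.02, 0.25)
    contrast_delta: float = 25.0  # mean lesion-background intensity offset
    texture_scale: float = 6.0  # smoothing sigma of the background texture
    texture_std: float = 10.0  # intensity std of the background texture
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_area_fraction
        if not (0 < lo <= hi):
            raise ValueError("lesion_area_fraction must satisfy 0 < lo <= hi")
        if self.n_images < 1 or self.image_size < 16:
            raise ValueError("need n_images >= 1 and image_size >= 16")
        # the largest requested lesion must fit inside the frame with margin
        max_semi_axis = np.sqrt(hi * self.image_size**2 * 1.6 / np.pi)
        if max_semi_axis > 0.45 * self.image_size:
            raise ValueError(
                f"lesion_area_fraction {hi} infeasible for image_size {self.image_size}"
            )
        if self.lesions_per_image[0] < 1 or self.lesions_per_image[0] > self.lesions_per_image[1]:
            raise ValueError("lesions_per_image must be an increasing range from >= 1")


def _lesion_mask(size: int, area_px: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of one deformed ellipse of approximately ``area_px``."""
    aspect = rng.uniform(0.6, 1.6)
    a = np.sqrt(area_px * aspect / np.pi)
    b = np.sqrt(area_px / (aspect * np.pi))
    theta = rng.uniform(0, np.pi)
    margin = max(a, b) + 1.0
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    # low-order radial harmonics deform the boundary without changing area much
    ks = np.array([2, 3, 4])
    amps = rng.uniform(0.0, 0.07, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)

    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    phi = np.arctan2(v / b, u / a)
    m = 1.0 + sum(c * np.cos(k * phi + p) for k, c, p in zip(ks, amps, phases))
    return rho <= m


def generate_synthetic(cfg: SynthConfig) -> "list[SegmentationSample]":
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size
    samples = []
    for idx in range(cfg.n_images):
        tone = _BASE_TONE + rng.uniform(-15, 15, size=3)
        field = ndimage.gaussian_filter(rng.normal(size=(size, size)), cfg.texture_scale)
        sd = field.std()
        field = field / sd * cfg.texture_std if sd > 0 else field
        jitter = ndimage.gaussian_filter(
            rng.normal(scale=0.3 * cfg.texture_std, size=(size, size, 3)), (2, 2, 0)
        )
        img = tone[None, None, :] + field[:, :, None] + jitter

        n_lesions = int(rng.integers(cfg.lesions_per_image[0], cfg.lesions_per_image[1] + 1))
        mask = np.zeros((size, size), dtype=bool)
        for _ in range(n_lesions):
            frac = rng.uniform(*cfg.lesion_area_fraction)
            mask |= _lesion_mask(size, frac * size * size, rng)
        # feathered intensity bump on the image; the mask itself stays exact
        soft = ndimage.gaussian_filter(mask.astype(np.float32), 1.0)
        direction = np.array([1.0, 0.8, 0.9])  # lesions skew slightly red
        img = img + cfg.contrast_delta * soft[:, :, None] * direction[None, None, :]

        samples.append(
            SegmentationSample(
                np.clip(np.round(img), 0, 255).astype(np.uint8),
                mask.astype(np.uint8),
                f"synth_{cfg.seed}_{idx:05d}",
            )
        )
    return samples
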