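"""Dataset loading, deterministic splitting and geometric augmentation.

Samples are image/mask pairs: an H x W x 3 uint8 endoscopic frame and a
strictly binary H x W mask (nonzero = lesion).  Loading resizes images
bilinearly and masks with nearest neighbour followed by re-binarisation,
matching the 256 x 256 protocol used for training and evaluation.
Augmentation applies the same random rotation (default within +/-90
degrees) and horizontal/vertical flips (p = 0.5 each) to image and mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

logger = logging.getLogger(__name__)

_IMG_EXTS = (".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff")


@dataclass
class SegmentationSample:
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8, values in {0, 1}
    identifier: str

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"{self.identifier}: image {self.image.shape[:2]} and mask "
                f"{self.mask.shape} extents differ"
            )
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError(f"{self.identifier}: mask is not binary")


@dataclass
class SplitSpec:
    """Train/val/test fractions plus the seed fixing the assignment."""

    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.ratios) - 1.0) > 1e-9 or any(r < 0 for r in self.ratios):
            raise ValueError("split fractions must be nonnegative and sum to 1")


def split_sizes(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    """Val and test round up, train takes the remainder."""
    n_val = int(np.ceil(n * spec.ratios[1]))
    n_test = int(np.ceil(n * spec.ratios[2]))
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ValueError(f"cannot split {n} samples with ratios {spec.ratios}")
    return n_train, n_val, n_test


def split_dataset(
    samples: "list[SegmentationSample]", spec: SplitSpec
) -> dict[str, list[SegmentationSample]]:
    """Deterministic, leak-free partition into train/val/test."""
    n_train, n_val, n_test = split_sizes(len(samples), spec)
    order = np.random.default_rng(spec.seed).permutation(len(samples))
    shuffled = [samples[i] for i in order]
    return {
        "train": shuffled[:n_train],
        "val": shuffled[n_train : n_train + n_val],
        "test": shuffled[n_train + n_val :],
    }


def load_dataset(image_dir, mask_dir, size: int = 256) -> "list[SegmentationSample]":
    """Load same-named image/mask pairs, resized to ``size`` x ``size``.

    Every image must have a mask of the same stem; failures are collected
    and reported per file.  Pairs are sorted by identifier.
    """
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    images = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in _IMG_EXTS
    ) if image_dir.is_dir() else []
    if not images:
        raise FileNotFoundError(f"no images found in {image_dir}")
    masks_by_stem = (
        {p.stem: p for p in mask_dir.iterdir() if p.suffix.lower() in _IMG_EXTS}
        if mask_dir.is_dir()
        else {}
    )
    samples, errors = [], []
    for img_path in images:
        mask_path = masks_by_stem.get(img_path.stem)
        if mask_path is None:
            errors.append(f"missing mask for {img_path}")
            continue
        try:
            img = Image.open(img_path).convert("RGB").resize((size, size), Image.BILINEAR)
            msk = Image.open(mask_path).convert("L").resize((size, size), Image.NEAREST)
        except OSError as e:
            errors.append(f"unreadable file for {img_path.stem}: {e}")
            continue
        mask = (np.asarray(msk, dtype=np.float32) / 255.0 >= 0.5).astype(np.uint8)
        samples.append(
            SegmentationSample(np.asarray(img, dtype=np.uint8), mask, img_path.stem)
        )
    if errors:
        raise FileNotFoundError("dataset errors:\n" + "\n".join(errors))
    return samples


@dataclass
class AugmentConfig:
    rotation_range: float = 90.0  # degrees, uniform in +/- range
    flip_prob: float = 0.5


def augment(
    sample: SegmentationSample,
    rng: np.random.Generator,
    cfg: AugmentConfig | None = None,
) -> SegmentationSample:
    """Random rotation and flips, identically applied to image and mask."""
    cfg = cfg or AugmentConfig()
    angle = float(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
    flip_h = bool(rng.random() < cfg.flip_prob)
    flip_v = bool(rng.random() < cfg.flip_prob)
    img = sample.image.astype(np.float32)
    msk = sample.mask.astype(np.float32)
    if angle != 0.0:
        img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False, order=1, mode="reflect")
        msk = ndimage.rotate(msk, angle, reshape=False, order=1, mode="constant", cval=0.0)
    if flip_h:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if flip_v:
        img, msk = img[::-1], msk[::-1]
    return SegmentationSample(
        np.clip(np.round(img), 0, 255).astype(np.uint8),
        (msk >= 0.5).astype(np.uint8),
        sample.identifier,
    )


def to_arrays(samples: "list[SegmentationSample]") -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into normalised (B,3,H,W) images and (B,1,H,W) masks."""
    x = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    y = np.stack([s.mask for s in samples]).astype(np.float32)
    return x.transpose(0, 3, 1, 2), y[:, None]
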