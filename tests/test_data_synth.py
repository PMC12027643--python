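"""Dataset I/O, deterministic splits, augmentation, and the synthetic generator."""

import numpy as np
import pytest
from PIL import Image

from mgraunet import (
    AugmentConfig,
    SegmentationSample,
    SplitSpec,
    SynthConfig,
    augment,
    generate_synthetic,
    load_dataset,
    split_dataset,
    split_sizes,
)


@pytest.fixture
def dataset_dirs(tmp_path, rng):
    img_dir, msk_dir = tmp_path / "images", tmp_path / "masks"
    img_dir.mkdir()
    msk_dir.mkdir()
    for i in range(3):
        img = rng.integers(0, 256, size=(40, 30, 3), dtype=np.uint8)
        mask = (rng.random((40, 30)) < 0.3).astype(np.uint8) * 255
        Image.fromarray(img).save(img_dir / f"case_{i}.png")
        Image.fromarray(mask).save(msk_dir / f"case_{i}.png")
    return img_dir, msk_dir


class TestLoad:
    def test_loads_resizes_and_binarizes(self, dataset_dirs):
        samples = load_dataset(*dataset_dirs, size=32)
        assert len(samples) == 3
        assert [s.identifier for s in samples] == sorted(s.identifier for s in samples)
        for s in samples:
            assert s.image.shape == (32, 32, 3) and s.mask.shape == (32, 32)
            assert set(np.unique(s.mask)) <= {0, 1}

    def test_missing_mask_reported_with_path(self, dataset_dirs):
        img_dir, msk_dir = dataset_dirs
        (msk_dir / "case_1.png").unlink()
        with pytest.raises(FileNotFoundError, match="case_1"):
            load_dataset(img_dir, msk_dir)

    def test_empty_directory_rejected(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(FileNotFoundError, match="no images"):
            load_dataset(tmp_path / "empty", tmp_path / "empty")


class TestSplit:
    def test_37_samples_split_29_4_4(self):
        assert split_sizes(37, SplitSpec(seed=7)) == (29, 4, 4)

    def test_sizes_by_enumeration_counting_oracle(self):
        spec = SplitSpec()
        for n in range(3, 100):
            tr, va, te = split_sizes(n, spec)
            assert tr + va + te == n
            # val/test take the ceiling of their share, train the remainder
            assert va == -((-n) // 10) and te == -((-n) // 10)

    def test_partition_is_exact_and_deterministic(self):
        samples = [
            SegmentationSample(
                np.zeros((8, 8, 3), np.uint8), np.zeros((8, 8), np.uint8), f"s{i}"
            )
            for i in range(37)
        ]
        a = split_dataset(samples, SplitSpec(seed=7))
        b = split_dataset(samples, SplitSpec(seed=7))
        ids = lambda d: {k: [s.identifier for s in v] for k, v in d.items()}
        assert ids(a) == ids(b)
        all_ids = sum(ids(a).values(), [])
        assert sorted(all_ids) == sorted(s.identifier for s in samples)
        assert len(set(all_ids)) == 37  # no leakage between splits


class TestAugment:
    def _sample(self, rng, size=32, lesion=None):
        img = rng.integers(0, 256, size=(size, size, 3), dtype=np.uint8)
        mask = np.zeros((size, size), np.uint8)
        t, b, l, r = lesion or (8, 20, 10, 22)
        mask[t:b, l:r] = 1
        return SegmentationSample(img, mask, "a")

    def test_zero_rotation_no_flip_is_identity(self, rng):
        s = self._sample(rng)

        class FixedRng:
            def uniform(self, lo, hi):
                return 0.0

            def random(self):
                return 1.0  # never below flip_prob

        out = augment(s, FixedRng())
        np.testing.assert_array_equal(out.image, s.image)
        np.testing.assert_array_equal(out.mask, s.mask)

    def test_double_flip_is_involution(self, rng):
        s = self._sample(rng)

        class FlipOnly:
            def uniform(self, lo, hi):
                return 0.0

            def random(self):
                return 0.0  # always flip

        once = augment(s, FlipOnly())
        twice = augment(once, FlipOnly())
        np.testing.assert_array_equal(twice.image, s.image)
        np.testing.assert_array_equal(twice.mask, s.mask)

    def test_mask_pixel_count_conserved(self, rng):
        s = self._sample(rng, size=48, lesion=(12, 34, 14, 36))
        area = s.mask.sum()
        pure_flips = AugmentConfig(rotation_range=0.0)
        for _ in range(50):
            assert augment(s, rng, pure_flips).mask.sum() == area
        for _ in range(50):
            out = augment(s, rng)  # rotation: interpolation tolerance
            assert abs(int(out.mask.sum()) - int(area)) <= 0.02 * area

    def test_image_and_mask_transform_jointly(self, rng):
        # mark a distinctive corner and check image/mask stay aligned
        s = self._sample(rng, size=32)
        img = s.image.copy()
        img[8:20, 10:22] = 255
        s = SegmentationSample(img, s.mask, "joint")
        for _ in range(10):
            out = augment(s, rng, AugmentConfig(rotation_range=0.0))
            assert (out.image[out.mask == 1] == 255).all()


class TestSyntheticGenerator:
    def test_same_seed_bitwise_identical(self):
        cfg = SynthConfig(n_images=4, image_size=32, seed=9)
        a, b = generate_synthetic(cfg), generate_synthetic(cfg)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.image, sb.image)
            np.testing.assert_array_equal(sa.mask, sb.mask)
            assert sa.identifier == sb.identifier

    def test_fixed_area_fraction_bounds_mask_area(self):
        cfg = SynthConfig(
            n_images=20,
            image_size=64,
            lesions_per_image=(1, 1),
            lesion_area_fraction=(0.05, 0.05),
            seed=3,
        )
        for s in generate_synthetic(cfg):
            frac = s.mask.mean()
            assert 0.04 <= frac <= 0.06

    def test_masks_are_strictly_binary_and_nonempty(self):
        for s in generate_synthetic(SynthConfig(n_images=10, image_size=48, seed=5)):
            assert set(np.unique(s.mask)) == {0, 1}

    def test_zero_contrast_hides_lesion_within_texture_noise(self):
        cfg = SynthConfig(n_images=50, image_size=48, contrast_delta=0.0, seed=11)
        diffs = []
        for s in generate_synthetic(cfg):
            inside = s.image[s.mask == 1].mean()
            outside = s.image[s.mask == 0].mean()
            diffs.append(inside - outside)
        assert abs(np.mean(diffs)) < cfg.texture_std

    def test_positive_contrast_separates_lesion_mean(self):
        cfg = SynthConfig(n_images=20, image_size=48, contrast_delta=40.0, seed=11)
        for s in generate_synthetic(cfg):
            assert s.image[s.mask == 1].mean() > s.image[s.mask == 0].mean()

    def test_infeasible_area_fraction_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SynthConfig(image_size=32, lesion_area_fraction=(0.1, 0.8))
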