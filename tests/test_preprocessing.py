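import numpy as np
import pytest

from bandelet import (
    AugmentConfig,
    LabelledImageSet,
    augment_to_target,
    balance_dataset,
    smote_oversample,
    split_dataset,
)
from bandelet.preprocessing import load_image_folder, save_image_folder


def _images(n, shape=(16, 16), seed=0):
    rng = np.random.default_rng(seed)
    return [rng.uniform(0, 255, shape) for _ in range(n)]


class TestSmote:
    def test_doubles_fourteen_to_twentyeight(self):
        out, prov = smote_oversample(_images(14), 28, k_neighbors=5, seed=1)
        assert len(out) == 28
        assert prov.count("real") == 14
        assert prov.count("smote") == 14

    def test_target_equal_to_count_is_identity(self):
        imgs = _images(5)
        out, prov = smote_oversample(imgs, 5, k_neighbors=2, seed=0)
        assert len(out) == 5 and all(p == "real" for p in prov)
        for a, b in zip(out, imgs):
            np.testing.assert_array_equal(a, b)

    def test_synthetic_samples_are_convex_combinations(self):
        imgs = _images(6, seed=3)
        out, prov = smote_oversample(imgs, 20, k_neighbors=3, seed=7)
        lo = np.min(np.stack(imgs), axis=0)
        hi = np.max(np.stack(imgs), axis=0)
        for img, p in zip(out, prov):
            if p == "smote":
                assert (img >= lo - 1e-9).all() and (img <= hi + 1e-9).all()

    def test_deterministic_given_seed(self):
        imgs = _images(6)
        a, _ = smote_oversample(imgs, 12, 3, seed=42)
        b, _ = smote_oversample(imgs, 12, 3, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_rejects_invalid_arguments(self):
        imgs = _images(5)
        with pytest.raises(ValueError, match="k_neighbors"):
            smote_oversample(imgs, 10, k_neighbors=5, seed=0)
        with pytest.raises(ValueError, match="below"):
            smote_oversample(imgs, 3, k_neighbors=2, seed=0)
        with pytest.raises(ValueError):
            smote_oversample(_images(1), 4, 1, seed=0)


class TestBalance:
    def test_counts_from_oversampled_input(self):
        balanced = balance_dataset(_images(28), _images(62, seed=9), 28)
        assert len(balanced) == 56
        assert balanced.class_counts() == (28, 28)

    def test_zero_per_class_gives_empty_set(self):
        out = balance_dataset(_images(3), _images(3), 0)
        assert len(out) == 0

    def test_majority_truncated_in_stable_order(self):
        majority = _images(10, seed=4)
        out = balance_dataset(_images(4), majority, 4)
        for img, expected in zip(out.images[4:], majority[:4]):
            np.testing.assert_array_equal(img, expected)

    def test_rejects_insufficient_items(self):
        with pytest.raises(ValueError):
            balance_dataset(_images(3), _images(10), 4)


class TestAugment:
    @pytest.fixture
    def base56(self):
        return LabelledImageSet(
            images=_images(56, (32, 32)),
            labels=[0] * 28 + [1] * 28,
            provenance=["real"] * 56,
        )

    def test_reaches_exact_target(self, base56):
        cfg = AugmentConfig(out_size=64)
        out = augment_to_target(base56, 200, cfg, seed=5)
        assert len(out) == 200
        assert out.provenance.count("augmented") == 144

    def test_target_equal_to_size_is_identity(self, base56):
        out = augment_to_target(base56, 56, AugmentConfig(out_size=64), seed=0)
        assert out is base56

    def test_outputs_resized_and_clipped(self, base56):
        cfg = AugmentConfig(out_size=48)
        out = augment_to_target(base56, 80, cfg, seed=2)
        for img in out.images:
            assert img.shape == (48, 48)
            assert img.min() >= 0.0 and img.max() <= 255.0

    def test_class_proportions_preserved(self, base56):
        out = augment_to_target(base56, 201, AugmentConfig(out_size=32), seed=3)
        n0, n1 = out.class_counts()
        assert abs(n0 - n1) <= 1

    def test_deterministic_given_seed(self, base56):
        cfg = AugmentConfig(out_size=32)
        a = augment_to_target(base56, 100, cfg, seed=11)
        b = augment_to_target(base56, 100, cfg, seed=11)
        for x, y in zip(a.images, b.images):
            np.testing.assert_array_equal(x, y)

    def test_rejects_target_below_size(self, base56):
        with pytest.raises(ValueError):
            augment_to_target(base56, 10, AugmentConfig(), seed=0)


class TestSplit:
    def test_paper_scale_split_sizes(self):
        ds = LabelledImageSet(
            images=[np.zeros((2, 2))] * 2048,
            labels=[0] * 1024 + [1] * 1024,
            provenance=["real"] * 2048,
        )
        train, val = split_dataset(ds, 0.8, seed=0)
        assert (len(train), len(val)) == (1638, 410)
        assert abs(train.class_counts()[0] - train.class_counts()[1]) <= 1

    def test_balanced_small_split(self):
        ds = LabelledImageSet(
            images=[np.zeros((2, 2))] * 10,
            labels=[0, 1] * 5,
            provenance=["real"] * 10,
        )
        train, val = split_dataset(ds, 0.5, seed=1)
        assert (len(train), len(val)) == (5, 5)
        # stratified within one item
        assert abs(train.class_counts()[0] - train.class_counts()[1]) <= 1

    def test_partition_property(self):
        imgs = [np.full((2, 2), i) for i in range(20)]
        ds = LabelledImageSet(images=imgs, labels=[0] * 10 + [1] * 10,
                              provenance=["real"] * 20)
        train, val = split_dataset(ds, 0.7, seed=3)
        ids = sorted(int(im[0, 0]) for im in train.images + val.images)
        assert ids == list(range(20))
        train_ids = {int(im[0, 0]) for im in train.images}
        val_ids = {int(im[0, 0]) for im in val.images}
        assert not (train_ids & val_ids)

    def test_rejects_bad_fraction_and_tiny_class(self):
        ds = LabelledImageSet(images=[np.zeros((2, 2))] * 4,
                              labels=[0, 1, 1, 1], provenance=["real"] * 4)
        with pytest.raises(ValueError):
            split_dataset(ds, 1.5, seed=0)
        with pytest.raises(ValueError, match="fewer than 2"):
            split_dataset(ds, 0.5, seed=0)


class TestCountTrace:
    def test_full_pipeline_counts(self):
        """The canonical data program: 14 -> 28 -> 56 -> target -> 80/20,
        scaled to a small augmentation target for speed."""
        benign = _images(14, (16, 16), seed=1)
        malignant = _images(62, (16, 16), seed=2)
        over, prov = smote_oversample(benign, 28, 5, seed=3)
        balanced = balance_dataset(over, malignant, 28, prov)
        augmented = augment_to_target(balanced, 128, AugmentConfig(out_size=32), seed=4)
        train, val = split_dataset(augmented, 0.8, seed=5)
        assert (len(over), len(balanced), len(augmented)) == (28, 56, 128)
        assert (len(train), len(val)) == (102, 26)  # floor(0.8*128) = 102


def test_folder_round_trip(tmp_path):
    ds = LabelledImageSet(
        images=[np.full((8, 8), v, dtype=float) for v in (10, 20, 30)],
        labels=[0, 1, 1],
        provenance=["real", "real", "smote"],
    )
    save_image_folder(ds, tmp_path)
    loaded = load_image_folder(tmp_path)
    assert len(loaded) == 3
    assert loaded.class_counts() == (1, 2)
    assert (tmp_path / "manifest.tsv").exists()
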