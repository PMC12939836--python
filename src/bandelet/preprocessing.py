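"""Data program for the imbalanced two-class image set.

The stages mirror the standard recipe for a small, imbalanced ultrasound
collection: SMOTE-oversample the minority class to parity, combine equal
class counts, augment the balanced set to a fixed target with random
photometric/geometric perturbations, and split 80/20 stratified by label.
On the reference 14 benign / 62 malignant input the count trace is
14 -> 28 (SMOTE) -> 56 (balance) -> 2048 (augment) -> 1638/410 (split).

Every randomised stage is reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "LabelledImageSet",
    "AugmentConfig",
    "smote_oversample",
    "balance_dataset",
    "augment_to_target",
    "split_dataset",
    "load_image_folder",
    "save_image_folder",
]

BENIGN, MALIGNANT = 0, 1


@dataclass
class LabelledImageSet:
    """Greyscale images with binary labels and provenance tags.

    ``labels``: 0 = benign, 1 = malignant.  ``provenance`` per item is one
    of ``real``, ``smote``, ``augmented``.
    """

    images: list
    labels: list
    provenance: list
    seed: int = 0

    def __post_init__(self):
        if not (len(self.images) == len(self.labels) == len(self.provenance)):
            raise ValueError("images/labels/provenance must have equal length")
        if any(l not in (0, 1) for l in self.labels):
            raise ValueError("labels must be binary (0 benign, 1 malignant)")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx) -> "LabelledImageSet":
        return LabelledImageSet(
            images=[self.images[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            provenance=[self.provenance[i] for i in idx],
            seed=self.seed,
        )

    def class_counts(self) -> tuple[int, int]:
        labels = np.asarray(self.labels)
        return int((labels == 0).sum()), int((labels == 1).sum())


def smote_oversample(
    minority: list,
    target_count: int,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[list, list]:
    """SMOTE: synthesise minority images by convex interpolation.

    Each synthetic sample is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0, 1)``
    and ``x_nn`` one of the k nearest minority neighbours of ``x_i`` in
    pixel space.  Returns ``(images, provenance)`` of length exactly
    ``target_count`` with originals first.
    """
    n = len(minority)
    if n < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    if target_count < n:
        raise ValueError(f"target_count {target_count} below current count {n}")
    if not 1 <= k_neighbors <= n - 1:
        raise ValueError(f"k_neighbors must be in [1, {n - 1}], got {k_neighbors}")
    shapes = {np.asarray(im).shape for im in minority}
    if len(shapes) != 1:
        raise ValueError("SMOTE requires images of identical shape")
    shape = shapes.pop()
    if target_count == n:
        return list(minority), ["real"] * n

    X = np.stack([np.asarray(im, dtype=float).ravel() for im in minority])
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    # Drop each point's self-match in column 0.
    neighbour_idx = nn.kneighbors(X, return_distance=False)[:, 1:]

    rng = np.random.default_rng(seed)
    out = list(minority)
    prov = ["real"] * n
    for j in range(target_count - n):
        i = int(rng.integers(0, n))
        nn_choice = int(neighbour_idx[i, rng.integers(0, k_neighbors)])
        u = rng.uniform(0.0, 1.0)
        x_new = X[i] + u * (X[nn_choice] - X[i])
        out.append(x_new.reshape(shape))
        prov.append("smote")
    return out, prov


def balance_dataset(
    minority_images: list,
    majority_images: list,
    per_class: int,
    minority_prov: list | None = None,
) -> LabelledImageSet:
    """Take the first ``per_class`` of each class (majority truncated in its
    stable input order) and attach labels: minority -> 0, majority -> 1."""
    if per_class < 0:
        raise ValueError("per_class must be nonnegative")
    if minority_prov is None:
        minority_prov = ["real"] * len(minority_images)
    if len(minority_images) < per_class or len(majority_images) < per_class:
        raise ValueError(
            f"need at least {per_class} items per class, have "
            f"{len(minority_images)}/{len(majority_images)}"
        )
    images = list(minority_images[:per_class]) + list(majority_images[:per_class])
    labels = [BENIGN] * per_class + [MALIGNANT] * per_class
    prov = list(minority_prov[:per_class]) + ["real"] * per_class
    return LabelledImageSet(images=images, labels=labels, provenance=prov)


@dataclass(frozen=True)
class AugmentConfig:
    """Ranges of the random augmentation ops (each applied with p = 0.5)."""

    brightness_range: tuple[float, float] = (0.8, 1.2)
    rotation_deg: float = 15.0
    height_scale_range: tuple[float, float] = (0.9, 1.1)
    out_size: int = 512
    op_probability: float = 0.5


def _augment_one(image: np.ndarray, cfg: AugmentConfig, rng) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if rng.uniform() < cfg.op_probability:  # brightness
        img = img * rng.uniform(*cfg.brightness_range)
    if rng.uniform() < cfg.op_probability:  # horizontal flip
        img = img[:, ::-1]
    if rng.uniform() < cfg.op_probability:  # rotation, nearest fill at borders
        angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
        img = _sk_rotate(img, angle, resize=False, mode="edge",
                         order=1, preserve_range=True)
    if rng.uniform() < cfg.op_probability:  # height scaling, nearest fill
        factor = rng.uniform(*cfg.height_scale_range)
        h, w = img.shape
        new_h = max(1, int(round(h * factor)))
        scaled = _sk_resize(img, (new_h, w), order=1, mode="edge",
                            preserve_range=True, anti_aliasing=new_h < h)
        if new_h >= h:  # centre crop back to h
            top = (new_h - h) // 2
            img = scaled[top:top + h]
        else:           # pad with nearest (edge-replicated) rows
            pad_top = (h - new_h) // 2
            img = np.pad(scaled, ((pad_top, h - new_h - pad_top), (0, 0)), mode="edge")
    img = _sk_resize(img, (cfg.out_size, cfg.out_size), order=1, mode="edge",
                     preserve_range=True, anti_aliasing=True)
    return np.clip(img, 0.0, 255.0)


def augment_to_target(
    dataset: LabelledImageSet,
    target_total: int,
    ops_config: AugmentConfig | None = None,
    seed: int = 0,
) -> LabelledImageSet:
    """Grow the dataset to ``target_total`` items by random augmentation.

    Originals are retained (resized to the output size); new items cycle
    round-robin over the base images, so class proportions of the base set
    are preserved within one item.  Deterministic given ``seed``.
    """
    cfg = ops_config or AugmentConfig()
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot augment an empty dataset")
    if target_total < n:
        raise ValueError(f"target_total {target_total} below current size {n}")
    if target_total == n:
        return dataset

    rng = np.random.default_rng(seed)
    images = [
        np.clip(
            _sk_resize(np.asarray(im, dtype=float), (cfg.out_size, cfg.out_size),
                       order=1, mode="edge", preserve_range=True, anti_aliasing=True),
            0.0, 255.0,
        )
        for im in dataset.images
    ]
    labels = list(dataset.labels)
    prov = list(dataset.provenance)
    # Cycle per-class over the base images, interleaving classes in
    # proportion to the base composition (largest-deficit first) so class
    # proportions stay within one item at every prefix.
    class_idx = {c: [i for i, l in enumerate(dataset.labels) if l == c]
                 for c in sorted(set(dataset.labels))}
    frac = {c: len(idx) / n for c, idx in class_idx.items()}
    cursor = {c: 0 for c in class_idx}
    generated = {c: 0 for c in class_idx}
    while len(images) < target_total:
        total_gen = sum(generated.values()) + 1
        c = max(class_idx, key=lambda c: (frac[c] * total_gen - generated[c], -c))
        idx = class_idx[c][cursor[c] % len(class_idx[c])]
        cursor[c] += 1
        generated[c] += 1
        images.append(_augment_one(dataset.images[idx], cfg, rng))
        labels.append(dataset.labels[idx])
        prov.append("augmented")
    return LabelledImageSet(images=images, labels=labels, provenance=prov, seed=seed)


def split_dataset(
    dataset: LabelledImageSet,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[LabelledImageSet, LabelledImageSet]:
    """Stratified train/validation split.

    The train size is ``floor(train_fraction * N)`` (so 2048 at 0.8 gives
    1638/410), allocated across classes by largest remainder; the two parts
    partition the dataset and are deterministic given ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    labels = np.asarray(dataset.labels)
    n = len(dataset)
    n_train = int(np.floor(train_fraction * n))
    rng = np.random.default_rng(seed)

    class_idx = {}
    for c in (0, 1):
        idx = np.where(labels == c)[0]
        if idx.size > 0 and idx.size < 2:
            raise ValueError(f"class {c} has fewer than 2 items; cannot stratify")
        class_idx[c] = idx

    # Largest-remainder allocation of n_train across classes.
    quotas = {c: train_fraction * idx.size for c, idx in class_idx.items() if idx.size}
    take = {c: int(np.floor(q)) for c, q in quotas.items()}
    shortfall = n_train - sum(take.values())
    for c in sorted(quotas, key=lambda c: quotas[c] - take[c], reverse=True):
        if shortfall <= 0:
            break
        take[c] += 1
        shortfall -= 1

    train_idx, val_idx = [], []
    for c, idx in class_idx.items():
        if idx.size == 0:
            continue
        perm = rng.permutation(idx)
        train_idx.extend(perm[: take[c]])
        val_idx.extend(perm[take[c]:])
    train_idx.sort()
    val_idx.sort()
    return dataset.subset(train_idx), dataset.subset(val_idx)


# ---------------------------------------------------------------------------
# Folder I/O: root/{benign,malignant}/*.png with a manifest table.

def load_image_folder(root) -> LabelledImageSet:
    """Load ``root/{benign,malignant}/*.png`` (stable file-name order)."""
    from PIL import Image

    root = Path(root)
    images, labels, prov = [], [], []
    for label, sub in ((BENIGN, "benign"), (MALIGNANT, "malignant")):
        folder = root / sub
        if not folder.is_dir():
            continue
        for p in sorted(folder.glob("*.png")) + sorted(folder.glob("*.jpg")):
            img = np.asarray(Image.open(p).convert("L"), dtype=float)
            images.append(img)
            labels.append(label)
            prov.append("real")
    if not images:
        raise ValueError(f"no images found under {root}")
    return LabelledImageSet(images=images, labels=labels, provenance=prov)


def save_image_folder(dataset: LabelledImageSet, root, manifest_name="manifest.tsv") -> None:
    """Write PNGs into ``root/{benign,malignant}`` plus a provenance manifest."""
    from PIL import Image

    root = Path(root)
    rows = []
    counters = {0: 0, 1: 0}
    for img, label, prov in zip(dataset.images, dataset.labels, dataset.provenance):
        sub = "benign" if label == BENIGN else "malignant"
        (root / sub).mkdir(parents=True, exist_ok=True)
        name = f"{sub}_{counters[label]:05d}.png"
        counters[label] += 1
        arr = np.clip(np.asarray(img, dtype=float), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(root / sub / name)
        rows.append((f"{sub}/{name}", label, prov))
    with open(root / manifest_name, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["path", "label", "provenance"])
        writer.writerows(rows)
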