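"""Run configuration and the end-to-end pipeline.

A run is fully described by a flat YAML config (every key optional; unknown
keys rejected) plus one global seed.  Per-stage seeds are derived from the
global seed by hashing the stage name, so any stage can be re-run in
isolation and the whole run is reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .classify import TrainingConfig, train_classifier
from .features import (
    FeatureParams,
    apply_normalizer,
    extract_bandelet_tensor,
    fit_normalizer,
)
from .metrics import compute_metrics
from .preprocessing import (
    AugmentConfig,
    augment_to_target,
    balance_dataset,
    load_image_folder,
    smote_oversample,
    split_dataset,
)
from .quadtree import TransformParams

__all__ = ["RunConfig", "load_config", "derive_seed", "run_pipeline"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    # transform
    wavelet_name: str = "db2"
    levels: int = 1
    T: float = 30.0
    lam: float = 4.0
    n_directions: int = 16
    max_slope: float = 2.0
    min_block: int = 4
    # features
    work_size: int = 512
    tensor_size: int = 224
    # preprocessing
    smote_target: int = 28
    per_class: int = 28
    k_neighbors: int = 5
    target_total: int = 2048
    augment_out_size: int = 512
    train_fraction: float = 0.8
    split_before_augment: bool = False
    # synthetic input (used when no image folder is given)
    n_benign: int = 14
    n_malignant: int = 62
    phantom_size: int = 256
    # training
    freeze_epochs: int = 3
    total_epochs: int = 20
    learning_rate: float = 0.05
    lam_mix: float = 0.0
    batch_size: int = 16
    # global
    seed: int = 0

    def __post_init__(self):
        if self.T < 0:
            raise ValueError(f"T must be nonnegative, got {self.T}")
        if self.lam <= 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        if not 0 < self.train_fraction < 1:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.min_block < 2:
            raise ValueError(f"min_block must be >= 2, got {self.min_block}")
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        if not 0 <= self.lam_mix <= 1:
            raise ValueError(f"lam_mix must be in [0, 1], got {self.lam_mix}")

    def transform_params(self) -> TransformParams:
        return TransformParams(
            wavelet_name=self.wavelet_name, levels=self.levels, T=self.T,
            lam=self.lam, n_directions=self.n_directions,
            max_slope=self.max_slope, min_block=self.min_block,
        )

    def feature_params(self) -> FeatureParams:
        return FeatureParams(
            work_size=self.work_size, tensor_size=self.tensor_size,
            transform=self.transform_params(),
        )

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(
            freeze_epochs=self.freeze_epochs, total_epochs=self.total_epochs,
            learning_rate=self.learning_rate, lam_mix=self.lam_mix,
            batch_size=self.batch_size, seed=derive_seed(self.seed, "train"),
        )


def load_config(path) -> RunConfig:
    """Load a YAML config; unknown keys and out-of-range values rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping of keys to values")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def run_pipeline(
    config: RunConfig,
    out_dir,
    input_dir=None,
    dry_run: bool = False,
) -> dict:
    """Execute the full workflow and write its artefacts to ``out_dir``.

    Stages: load (or synthesise) the imbalanced input set, SMOTE-balance,
    augment, split, extract bandelet tensors, fit/apply the normaliser on
    the training split, train the classifier, and evaluate.  Returns (and
    writes) a machine-readable summary including the count trace.
    """
    if dry_run:
        return {"config": asdict(config), "dry_run": True}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        if input_dir is not None:
            dataset = load_image_folder(input_dir)
        else:
            from .phantom import generate_dataset

            dataset = generate_dataset(
                config.n_benign, config.n_malignant,
                seed=derive_seed(config.seed, "synth"),
                size=(config.phantom_size, config.phantom_size),
            )
        benign = [im for im, l in zip(dataset.images, dataset.labels) if l == 0]
        malignant = [im for im, l in zip(dataset.images, dataset.labels) if l == 1]
        n_benign_initial = len(benign)

        stage = "smote"
        over, prov = smote_oversample(
            benign, config.smote_target, config.k_neighbors,
            seed=derive_seed(config.seed, "smote"),
        )
        n_after_smote = len(over)

        stage = "balance"
        balanced = balance_dataset(over, malignant, config.per_class, prov)
        n_balanced = len(balanced)

        aug_cfg = AugmentConfig(out_size=config.augment_out_size)
        if config.split_before_augment:
            # Methodologically safer variant: split the balanced base set
            # first, then augment each side independently (no augmented
            # siblings across the split boundary).
            stage = "split"
            base_train, base_val = split_dataset(
                balanced, config.train_fraction, seed=derive_seed(config.seed, "split"))
            stage = "augment"
            n_train_target = int(np.floor(config.train_fraction * config.target_total))
            train_set = augment_to_target(
                base_train, n_train_target, aug_cfg, seed=derive_seed(config.seed, "aug-train"))
            val_set = augment_to_target(
                base_val, config.target_total - n_train_target, aug_cfg,
                seed=derive_seed(config.seed, "aug-val"))
            n_augmented = len(train_set) + len(val_set)
        else:
            stage = "augment"
            augmented = augment_to_target(
                balanced, config.target_total, aug_cfg,
                seed=derive_seed(config.seed, "augment"))
            n_augmented = len(augmented)
            stage = "split"
            train_set, val_set = split_dataset(
                augmented, config.train_fraction, seed=derive_seed(config.seed, "split"))

        stage = "features"
        fparams = config.feature_params()
        train_tensors = [extract_bandelet_tensor(im, fparams) for im in train_set.images]
        val_tensors = [extract_bandelet_tensor(im, fparams) for im in val_set.images]

        stage = "normalise"
        norm = fit_normalizer(train_tensors)
        train_x = np.stack([apply_normalizer(t, norm).channels for t in train_tensors])
        val_x = np.stack([apply_normalizer(t, norm).channels for t in val_tensors])
        train_y = np.asarray(train_set.labels)
        val_y = np.asarray(val_set.labels)

        stage = "train"
        model, history = train_classifier((train_x, train_y), (val_x, val_y),
                                          config.training_config())

        stage = "evaluate"
        report = compute_metrics(val_y, model.predict(val_x))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    summary = {
        "config": asdict(config),
        "count_trace": {
            "n_benign_initial": n_benign_initial,
            "n_after_smote": n_after_smote,
            "n_balanced": n_balanced,
            "n_augmented": n_augmented,
            "n_train": len(train_set),
            "n_val": len(val_set),
        },
        "normalizer": {"mu": list(norm.mu), "sigma": list(norm.sigma)},
        "metrics": report.as_dict(),
        "history": history,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    dump_config(config, out_dir / "config.yaml")
    with open(out_dir / "metrics.tsv", "w") as fh:
        fh.write("Accuracy\tSensitivity\tSpecificity\tF1\tPrecision\n")
        fh.write("\t".join(
            "-" if v is None else f"{v:.4f}"
            for v in (report.Acc, report.Sen, report.Spe, report.F1, report.P)
        ) + "\n")
    with open(out_dir / "history.tsv", "w") as fh:
        fh.write("epoch\ttrain_loss\ttrain_acc\tval_loss\tval_acc\n")
        for i in range(len(history["train_loss"])):
            fh.write(f"{i}\t{history['train_loss'][i]:.6f}\t{history['train_acc'][i]:.4f}"
                     f"\t{history['val_loss'][i]:.6f}\t{history['val_acc'][i]:.4f}\n")
    return summary
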