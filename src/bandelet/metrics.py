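"""Binary-classification metrics and repeated k-fold descriptive statistics.

Conventions: the positive class is malignant (label 1).  All five metrics
are percentages derived from the confusion counts:

    Acc = (TP + TN) / N * 100        Sen = TP / (TP + FN) * 100
    Spe = TN / (TN + FP) * 100       P   = TP / (TP + FP) * 100
    F1  = 2 * P * Sen / (P + Sen)

A ratio with a zero denominator is reported as absent (None), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "MetricsReport",
    "FoldStatistics",
    "compute_metrics",
    "fold_statistics",
    "cross_validate",
]


@dataclass(frozen=True)
class MetricsReport:
    TP: int
    TN: int
    FP: int
    FN: int
    Acc: float | None
    Sen: float | None
    Spe: float | None
    P: float | None
    F1: float | None

    @property
    def N(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "Acc": self.Acc, "Sen": self.Sen, "Spe": self.Spe,
            "P": self.P, "F1": self.F1,
        }


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """Confusion counts and the five percentage metrics."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1D vectors")
    if y_true.size == 0:
        raise ValueError("empty input")
    for v in (y_true, y_pred):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    def ratio(num, den):
        return None if den == 0 else 100.0 * num / den

    acc = ratio(tp + tn, tp + tn + fp + fn)
    sen = ratio(tp, tp + fn)
    spe = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    if prec is None or sen is None or (prec + sen) == 0:
        f1 = None
    else:
        f1 = 2.0 * prec * sen / (prec + sen)
    return MetricsReport(TP=tp, TN=tn, FP=fp, FN=fn,
                         Acc=acc, Sen=sen, Spe=spe, P=prec, F1=f1)


@dataclass(frozen=True)
class FoldStatistics:
    """Descriptive statistics of one metric across folds."""

    mean: float
    median: float
    variance: float
    std: float
    q1: float
    q3: float
    min: float
    max: float

    def as_dict(self) -> dict:
        return {
            "mean": self.mean, "median": self.median, "variance": self.variance,
            "std": self.std, "q1": self.q1, "q3": self.q3,
            "min": self.min, "max": self.max,
        }


def fold_statistics(values) -> FoldStatistics:
    """Mean, median, variance, std, quartiles (linear interpolation),
    min and max across folds."""
    values = np.asarray([v for v in values], dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 fold values")
    return FoldStatistics(
        mean=float(values.mean()),
        median=float(np.median(values)),
        variance=float(values.var()),
        std=float(values.std()),
        q1=float(np.percentile(values, 25)),
        q3=float(np.percentile(values, 75)),
        min=float(values.min()),
        max=float(values.max()),
    )


def cross_validate(tensors, labels, k, repeats, config, train_fn=None):
    """Repeated stratified k-fold cross-validation.

    ``train_fn(train, val, config) -> (model, history)`` defaults to
    :func:`bandelet.classify.train_classifier`.  Returns ``(per-metric
    FoldStatistics dict, list of per-fold MetricsReport)``.
    """
    from dataclasses import replace

    from .classify import train_classifier

    if train_fn is None:
        train_fn = train_classifier
    x = np.asarray(tensors, dtype=float)
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) below k={k}")

    reports = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed + rep)
        for fold_i, (train_idx, val_idx) in enumerate(skf.split(x, y)):
            cfg = replace_config_seed(config, config.seed + 1000 * rep + fold_i)
            model, _ = train_fn((x[train_idx], y[train_idx]),
                                (x[val_idx], y[val_idx]), cfg)
            y_pred = model.predict(x[val_idx])
            reports.append(compute_metrics(y[val_idx], y_pred))

    stats = {}
    for name in ("Acc", "Sen", "Spe", "P", "F1"):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if len(vals) >= 2:
            stats[name] = fold_statistics(vals)
    return stats, reports


def replace_config_seed(config, seed):
    from dataclasses import replace

    return replace(config, seed=int(seed) % (2**31 - 1))
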