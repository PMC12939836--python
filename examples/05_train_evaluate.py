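"""Train the small CNN on phantom bandelet tensors and evaluate.

A miniature end-to-end run: 60 phantoms, bandelet tensors, freeze-then-
unfreeze fine-tuning, and the five classification metrics plus per-fold
descriptive statistics from a quick cross-validation of the final epochs.
"""

import numpy as np

from bandelet import (
    FeatureParams,
    TrainingConfig,
    TransformParams,
    apply_normalizer,
    compute_metrics,
    extract_bandelet_tensor,
    fit_normalizer,
    fold_statistics,
    train_classifier,
)
from bandelet.phantom import generate_dataset

ds = generate_dataset(30, 30, seed=5, size=(64, 64))
fparams = FeatureParams(work_size=64, tensor_size=32,
                        transform=TransformParams(levels=1, T=30.0, n_directions=8))
tensors = [extract_bandelet_tensor(im, fparams) for im in ds.images]
labels = np.asarray(ds.labels)

rng = np.random.default_rng(0)
idx0 = rng.permutation(np.where(labels == 0)[0])
idx1 = rng.permutation(np.where(labels == 1)[0])
tr = np.concatenate([idx0[:24], idx1[:24]])
va = np.concatenate([idx0[24:], idx1[24:]])

norm = fit_normalizer([tensors[i] for i in tr])
x = np.stack([apply_normalizer(t, norm).channels for t in tensors])

cfg = TrainingConfig(total_epochs=15, freeze_epochs=3, learning_rate=0.05, seed=1)
model, history = train_classifier((x[tr], labels[tr]), (x[va], labels[va]), cfg)

report = compute_metrics(labels[va], model.predict(x[va]))
stats = fold_statistics(history["val_acc"][-5:])

print(f"final val accuracy : {100 * history['val_acc'][-1]:.1f}%")
print(f"confusion counts   : TP={report.TP} TN={report.TN} "
      f"FP={report.FP} FN={report.FN}")
print(f"Acc/Sen/Spe/P/F1   : {report.Acc:.1f} / {report.Sen:.1f} / "
      f"{report.Spe:.1f} / {report.P:.1f} / {report.F1:.1f} %")
print(f"val-acc last 5 ep  : mean {100 * stats.mean:.1f}%, "
      f"std {100 * stats.std:.1f}%, range [{100 * stats.min:.1f}, "
      f"{100 * stats.max:.1f}]%")
print()
print("The convolutional base is bit-frozen for the first 3 epochs (only")
print("the head trains), then unfrozen at half the learning rate; metrics")
print("treat malignant (label 1) as the positive class.")
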