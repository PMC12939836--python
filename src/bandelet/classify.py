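"""Small CNN classifier and its fine-tuning contract.

The test backbone is a compact 3-block convolutional network (conv3x3 +
ReLU + 2x2 average pooling, then global average pooling and a linear head)
written directly on numpy so the whole pipeline trains on one CPU in
minutes.  Training follows the standard transfer-learning recipe: the
convolutional base is frozen for the first ``freeze_epochs`` (only the head
updates), then unfrozen and trained end-to-end at a reduced learning rate.
Optimisation is plain mini-batch gradient descent, ``theta <- theta -
alpha * grad``, on the softmax cross-entropy; an optional source/target
loss mixture ``L = lam_mix * L_source + (1 - lam_mix) * L_target`` supports
retaining source-task knowledge when a source batch stream is provided
(``lam_mix = 0``, the default, is pure target fine-tuning).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TrainingConfig", "SmallCNN", "train_classifier", "mixed_loss"]


@dataclass
class TrainingConfig:
    backbone: str = "small-cnn"
    freeze_epochs: int = 3
    total_epochs: int = 20
    learning_rate: float = 0.05
    unfreeze_lr_factor: float = 0.5
    batch_size: int = 16
    lam_mix: float = 0.0  # weight of the source loss in the mixture
    conv_channels: tuple[int, int, int] = (8, 16, 32)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.freeze_epochs <= self.total_epochs:
            raise ValueError("freeze_epochs must lie in [0, total_epochs]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.lam_mix <= 1.0:
            raise ValueError("lam_mix must lie in [0, 1]")


def _im2col(x, kh, kw):
    # x: (n, c, h, w), 'same' padding of 1 for 3x3 kernels
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, c, kh * kw, h, w))
    k = 0
    for i in range(kh):
        for j in range(kw):
            cols[:, :, k] = xp[:, :, i:i + h, j:j + w]
            k += 1
    return cols.reshape(n, c * kh * kw, h * w)


class _Conv3x3:
    """3x3 same-padding convolution with ReLU, backprop via im2col."""

    def __init__(self, c_in, c_out, rng):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.standard_normal((c_out, c_in * 9)) * scale
        self.b = np.zeros(c_out)

    def forward(self, x):
        n, c, h, w = x.shape
        self._cols = _im2col(x, 3, 3)          # (n, c*9, h*w)
        self._in_shape = x.shape
        z = np.einsum("oc,ncp->nop", self.W, self._cols) + self.b[None, :, None]
        z = z.reshape(n, -1, h, w)
        self._mask = z > 0
        return z * self._mask

    def backward(self, grad, lr, frozen):
        n, c_out, h, w = grad.shape
        grad = (grad * self._mask).reshape(n, c_out, h * w)
        if not frozen:
            gW = np.einsum("nop,ncp->oc", grad, self._cols) / n
            gb = grad.sum(axis=(0, 2)) / n
        # Gradient w.r.t. input (needed even when frozen, for deeper layers).
        gcols = np.einsum("oc,nop->ncp", self.W, grad)  # (n, c_in*9, h*w)
        c_in = self._in_shape[1]
        gcols = gcols.reshape(n, c_in, 9, h, w)
        gx = np.zeros((n, c_in, h + 2, w + 2))
        k = 0
        for i in range(3):
            for j in range(3):
                gx[:, :, i:i + h, j:j + w] += gcols[:, :, k]
                k += 1
        if not frozen:
            self.W -= lr * gW
            self.b -= lr * gb
        return gx[:, :, 1:-1, 1:-1]


class _AvgPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._shape = (n, c, h2 * 2, w2 * 2)
        xr = x[:, :, :h2 * 2, :w2 * 2].reshape(n, c, h2, 2, w2, 2)
        return xr.mean(axis=(3, 5))

    def backward(self, grad):
        n, c, h, w = self._shape
        g = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
        return g


class SmallCNN:
    """3-block CNN over 4-channel tensors; flatten + linear softmax head.

    The head is sized lazily on the first forward pass (the flattened
    feature dimension depends on the input resolution) from a seeded
    generator, so construction stays deterministic.
    """

    def __init__(self, in_channels=4, conv_channels=(8, 16, 32), seed=0):
        rng = np.random.default_rng(seed)
        chans = [in_channels, *conv_channels]
        self.convs = [_Conv3x3(chans[i], chans[i + 1], rng) for i in range(3)]
        self.pools = [_AvgPool2() for _ in range(3)]
        self._head_rng = rng
        self.W_head = None
        self.b_head = np.zeros(2)

    # -- inference ---------------------------------------------------------
    def logits(self, x):
        x = np.asarray(x, dtype=float)
        for conv, pool in zip(self.convs, self.pools):
            x = pool.forward(conv.forward(x))
        self._feat_shape = x.shape
        feats = x.reshape(x.shape[0], -1)
        if self.W_head is None:
            scale = np.sqrt(1.0 / feats.shape[1])
            self.W_head = self._head_rng.standard_normal((feats.shape[1], 2)) * scale
        self._feats = feats
        return feats @ self.W_head + self.b_head

    def predict(self, x):
        return np.argmax(self.logits(x), axis=1)

    @staticmethod
    def _softmax(z):
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss(self, x, y):
        p = self._softmax(self.logits(x))
        return float(-np.mean(np.log(p[np.arange(len(y)), y] + 1e-12)))

    # -- one SGD step ------------------------------------------------------
    def step(self, x, y, lr, frozen_base):
        z = self.logits(x)
        p = self._softmax(z)
        n = len(y)
        loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-12)))
        gz = p.copy()
        gz[np.arange(n), y] -= 1.0
        gz /= n
        gW = self._feats.T @ gz
        gb = gz.sum(axis=0)
        gf = gz @ self.W_head.T               # (n, flat)
        self.W_head -= lr * gW
        self.b_head -= lr * gb
        gx = gf.reshape(self._feat_shape)
        gx = gx * n  # undo the 1/n folded into gz; conv.backward re-averages
        for conv, pool in zip(reversed(self.convs), reversed(self.pools)):
            gx = pool.backward(gx)
            gx = conv.backward(gx, lr, frozen_base)
        return loss

    def conv_parameters(self):
        out = []
        for conv in self.convs:
            out.append(conv.W.copy())
            out.append(conv.b.copy())
        return out

    def state(self):
        return {
            **{f"conv{i}_W": c.W.copy() for i, c in enumerate(self.convs)},
            **{f"conv{i}_b": c.b.copy() for i, c in enumerate(self.convs)},
            "head_W": self.W_head.copy(),
            "head_b": self.b_head.copy(),
        }

    def load_state(self, state):
        for i, c in enumerate(self.convs):
            c.W = state[f"conv{i}_W"].copy()
            c.b = state[f"conv{i}_b"].copy()
        self.W_head = state["head_W"].copy()
        self.b_head = state["head_b"].copy()


def mixed_loss(model: SmallCNN, target_batch, source_batch, lam_mix: float) -> float:
    """Weighted source/target objective ``lam * L_S + (1 - lam) * L_T``.

    At ``lam_mix = 0`` this is exactly the target loss; at 1, the source
    loss.  ``source_batch`` may be None when ``lam_mix = 0``.
    """
    xt, yt = target_batch
    lt = model.loss(xt, yt)
    if lam_mix == 0.0:
        return lt
    if source_batch is None:
        raise ValueError("lam_mix > 0 requires a source batch")
    xs, ys = source_batch
    return lam_mix * model.loss(xs, ys) + (1.0 - lam_mix) * lt


def _accuracy(model, x, y):
    return float(np.mean(model.predict(x) == y))


def train_classifier(
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    config: TrainingConfig,
    source: tuple[np.ndarray, np.ndarray] | None = None,
    init_state: dict | None = None,
):
    """Fine-tune the small CNN; returns ``(model, history)``.

    ``train``/``val`` are ``(tensors, labels)`` with tensors shaped
    ``(n, 4, h, w)``.  ``init_state`` plays the role of source-task weights
    (random initialisation when absent).  History records per-epoch train
    and validation loss/accuracy.
    """
    x_train, y_train = np.asarray(train[0], dtype=float), np.asarray(train[1])
    x_val, y_val = np.asarray(val[0], dtype=float), np.asarray(val[1])
    if x_train.ndim != 4 or x_train.shape[1] != 4:
        raise ValueError(f"expected (n, 4, h, w) training tensors, got {x_train.shape}")
    if x_val.ndim != 4 or x_val.shape[1] != 4:
        raise ValueError(f"expected (n, 4, h, w) validation tensors, got {x_val.shape}")
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty split")

    rng = np.random.default_rng(config.seed)
    model = SmallCNN(in_channels=4, conv_channels=config.conv_channels,
                     seed=int(rng.integers(0, 2**31 - 1)))
    if init_state is not None:
        model.load_state(init_state)

    if config.lam_mix > 0.0 and source is None:
        raise ValueError("lam_mix > 0 requires source data")

    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    n = len(x_train)
    for epoch in range(config.total_epochs):
        frozen = epoch < config.freeze_epochs
        # Base learning rate while the conv base is frozen; reduced rate for
        # end-to-end fine-tuning after unfreezing.
        lr = config.learning_rate
        if not frozen and config.freeze_epochs > 0:
            lr *= config.unfreeze_lr_factor
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            # Gradient of lam * L_S + (1 - lam) * L_T, taken as two scaled
            # steps; lam_mix = 0 is a single pure-target step.
            loss = model.step(x_train[idx], y_train[idx],
                              lr * (1.0 - config.lam_mix), frozen)
            if config.lam_mix > 0.0:
                xs, ys = source
                sidx = rng.integers(0, len(xs), size=len(idx))
                model.step(np.asarray(xs, dtype=float)[sidx],
                           np.asarray(ys)[sidx], lr * config.lam_mix, frozen)
            epoch_loss += loss
            n_batches += 1
        history["train_loss"].append(epoch_loss / max(1, n_batches))
        history["train_acc"].append(_accuracy(model, x_train, y_train))
        history["val_loss"].append(model.loss(x_val, y_val))
        history["val_acc"].append(_accuracy(model, x_val, y_val))
    return model, history
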