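"""Seeded B-mode ultrasound phantoms with class-dependent nodule geometry.

Each phantom is a smooth tissue background with an embedded hypoechoic
(darker) nodule, corrupted by multiplicative speckle.  The two classes are
told apart by the clinical cues the generator encodes:

* benign nodules: near-elliptical, smooth boundary (low-amplitude, low-order
  radial harmonics), wider than tall;
* malignant nodules: irregular boundary (high-amplitude, high-order
  harmonics) and taller-than-wide axes.

Speckle is multiplicative with positive skew — ``x * (1 + s * eta)`` with
``eta`` a zero-mean, unit-variance shifted log-normal field — a standard
proxy for the signal-dependent interference of coherent ultrasound.

The default dataset imbalance (14 benign / 62 malignant) mirrors the class
balance of public thyroid B-mode collections, so the downstream SMOTE /
augmentation / split pipeline runs under realistic conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocessing import LabelledImageSet

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset"]


@dataclass
class PhantomSpec:
    """Geometry and noise parameters of one phantom.

    ``contrast`` is the relative echogenicity drop inside the nodule (0–1);
    ``boundary_amplitude`` is the radial modulation as a fraction of the
    nodule radius; ``speckle_scale`` the multiplicative noise strength.
    """

    size: tuple[int, int] = (256, 256)
    class_label: int = 0  # 0 = benign, 1 = malignant
    centre: tuple[float, float] | None = None
    axes: tuple[float, float] | None = None
    contrast: float = 0.45
    boundary_amplitude: float | None = None
    n_harmonics: int | None = None
    speckle_scale: float = 0.18
    seed: int = 0

    def resolved(self) -> "PhantomSpec":
        """Fill class-dependent defaults and validate geometry."""
        h, w = self.size
        rng = np.random.default_rng(self.seed)
        centre = self.centre or (
            h / 2 + rng.uniform(-0.05, 0.05) * h,
            w / 2 + rng.uniform(-0.05, 0.05) * w,
        )
        base = 0.22 * min(h, w)
        if self.axes is None:
            if self.class_label == 1:  # taller than wide
                axes = (base * rng.uniform(1.15, 1.4), base * rng.uniform(0.75, 0.95))
            else:
                axes = (base * rng.uniform(0.75, 0.95), base * rng.uniform(1.05, 1.3))
        else:
            axes = self.axes
        amp = self.boundary_amplitude
        harm = self.n_harmonics
        if self.class_label == 1:
            amp = 0.15 if amp is None else amp
            harm = 6 if harm is None else harm
        else:
            amp = 0.03 if amp is None else amp
            harm = 2 if harm is None else harm
        spec = PhantomSpec(
            size=self.size, class_label=self.class_label, centre=centre,
            axes=axes, contrast=self.contrast, boundary_amplitude=amp,
            n_harmonics=harm, speckle_scale=self.speckle_scale, seed=self.seed,
        )
        cy, cx = centre
        reach = max(axes) * (1 + amp)
        if cy - reach < 0 or cy + reach > h or cx - reach < 0 or cx + reach > w:
            raise ValueError("nodule does not fit inside the frame")
        if not 0 < self.contrast < 1:
            raise ValueError(f"contrast must lie in (0, 1), got {self.contrast}")
        return spec


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render one phantom as a float image in [0, 255].

    Deterministic given ``spec.seed``.  With ``speckle_scale = 0`` the image
    is piecewise smooth and the mean intensity inside the nodule sits below
    the surrounding tissue by at least the configured contrast.
    """
    spec = spec.resolved()
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)

    # Smooth tissue background: gentle depth gradient + blurred texture.
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    background = 150.0 + 30.0 * (yy / h - 0.5)
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 16)
    texture *= 12.0 / max(texture.std(), 1e-9)
    background = background + texture

    # Nodule mask: ellipse with harmonically modulated radius.
    cy, cx = spec.centre
    ay, ax = spec.axes
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    modulation = np.zeros_like(theta)
    for k in range(1, spec.n_harmonics + 1):
        phase = rng.uniform(0, 2 * np.pi)
        modulation += np.cos(k * theta + phase)
    if spec.n_harmonics > 0:
        modulation *= spec.boundary_amplitude / np.sqrt(spec.n_harmonics / 2)
    radius = np.sqrt((dy / ay) ** 2 + (dx / ax) ** 2)
    inside = radius <= 1.0 + modulation

    image = background * np.where(inside, 1.0 - spec.contrast, 1.0)

    if spec.speckle_scale > 0:
        # Zero-mean, unit-variance, positively skewed log-normal field.
        sigma_ln = 0.5
        ln = rng.lognormal(mean=0.0, sigma=sigma_ln, size=(h, w))
        mu = np.exp(sigma_ln ** 2 / 2)
        sd = np.sqrt((np.exp(sigma_ln ** 2) - 1) * np.exp(sigma_ln ** 2))
        eta = (ln - mu) / sd
        image = image * (1.0 + spec.speckle_scale * eta)

    return np.clip(image, 0.0, 255.0)


def generate_dataset(
    n_benign: int = 14,
    n_malignant: int = 62,
    seed: int = 0,
    size: tuple[int, int] = (256, 256),
    speckle_scale: float = 0.18,
) -> LabelledImageSet:
    """Seeded phantom dataset with the benign/malignant imbalance of public
    thyroid B-mode collections (defaults 14/62).

    Per-image seeds are derived from the dataset seed, so items are
    pairwise distinct and the whole set is reproducible.
    """
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_benign + n_malignant)
    images, labels, provenance = [], [], []
    for i in range(n_benign + n_malignant):
        label = 0 if i < n_benign else 1
        spec = PhantomSpec(
            size=size, class_label=label, seed=int(child_seeds[i]),
            speckle_scale=speckle_scale,
        )
        images.append(generate_phantom(spec))
        labels.append(label)
        provenance.append("real")
    return LabelledImageSet(images=images, labels=labels, provenance=provenance, seed=seed)
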