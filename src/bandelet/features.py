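"""Four-channel geometry-aware input tensors for the classifier.

An image is resized to a working resolution, bandelet-transformed, and
reduced to four coefficient-domain maps: the approximation grid (A) plus the
level-1 horizontal/vertical/diagonal detail grids (H, V, D) with each leaf's
bandelet coefficients placed back at their grid positions.  The maps are
resized to the classifier input size and stacked channel-wise, then z-scored
per channel with statistics fitted on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .flow import inverse_warp_order
from .quadtree import BandeletRepresentation, TransformParams, forward_bandelet

__all__ = [
    "FeatureParams",
    "BandeletTensor",
    "NormalizerParams",
    "resize_image",
    "coefficient_maps",
    "extract_bandelet_tensor",
    "fit_normalizer",
    "apply_normalizer",
    "save_tensors",
    "load_tensors",
]


@dataclass(frozen=True)
class FeatureParams:
    """Resolution and transform settings of tensor extraction.

    ``work_size`` is the resolution the transform runs at (512 matches
    common classifier preprocessing; smaller values scale the whole pipeline
    down proportionally); ``tensor_size`` the output channel resolution.
    """

    work_size: int = 512
    tensor_size: int = 224
    transform: TransformParams = TransformParams(levels=1)


@dataclass
class BandeletTensor:
    """Stack of 4 equally-sized channels in order (A, H, V, D)."""

    channels: np.ndarray  # (4, h, w)
    normalised: bool = False
    source_id: str = ""

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3 or self.channels.shape[0] != 4:
            raise ValueError(f"expected (4, h, w) channels, got {self.channels.shape}")

    @property
    def shape(self):
        return self.channels.shape


@dataclass(frozen=True)
class NormalizerParams:
    """Per-channel z-score statistics fitted on the training set."""

    mu: tuple[float, float, float, float]
    sigma: tuple[float, float, float, float]
    fitted_on: str = ""


def resize_image(image: np.ndarray, target: tuple[int, int], method: str = "bilinear") -> np.ndarray:
    """Resize with bilinear (order 1) or nearest (order 0) interpolation."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    th, tw = target
    if th <= 0 or tw <= 0:
        raise ValueError(f"target size must be positive, got {target}")
    if image.shape == (th, tw):
        return image.copy()
    order = {"bilinear": 1, "nearest": 0}.get(method)
    if order is None:
        raise ValueError(f"unknown resize method {method!r}")
    down = th < image.shape[0] or tw < image.shape[1]
    return _sk_resize(image, (th, tw), order=order, mode="edge",
                      preserve_range=True, anti_aliasing=down and order > 0)


def coefficient_maps(rep: BandeletRepresentation) -> tuple[np.ndarray, ...]:
    """(A, H, V, D) coefficient-domain grids of a representation.

    A is the coarsest approximation; H/V/D are the level-1 detail grids with
    bandelet coefficients of each leaf scattered back to the leaf's own grid
    positions (in warped-rank order along the leaf's flow), so the maps live
    in the coefficient domain rather than being partial reconstructions.
    """
    maps = [rep.ll.copy()]
    h1, w1 = rep.subband_shapes[0]
    for oi in range(3):
        tree = rep.trees[0][oi]
        side = tree.region[2]
        grid = np.zeros((side, side))
        for leaf in tree.leaves():
            x1, x2, lh, lw = leaf.region
            vec = rep.leaf_coeffs[(0, oi, leaf.region)]
            if leaf.flow is not None and leaf.flow.is_flow:
                inv = inverse_warp_order((lh, lw), leaf.flow.slope)
                block = vec[inv].reshape(lh, lw)
            else:
                block = vec.reshape(lh, lw)
            grid[x1:x1 + lh, x2:x2 + lw] = block
        maps.append(grid[:h1, :w1])
    return tuple(maps)


def extract_bandelet_tensor(
    image: np.ndarray,
    params: FeatureParams | None = None,
    source_id: str = "",
) -> BandeletTensor:
    """Image -> (4, tensor_size, tensor_size) bandelet tensor.

    Deterministic given (image, params).
    """
    params = params or FeatureParams()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a greyscale image")
    work = resize_image(image, (params.work_size, params.work_size))
    rep = forward_bandelet(work, params.transform)
    maps = coefficient_maps(rep)
    size = (params.tensor_size, params.tensor_size)
    channels = np.stack([resize_image(m, size) for m in maps])
    return BandeletTensor(channels=channels, source_id=source_id)


def fit_normalizer(tensors, fitted_on: str = "train") -> NormalizerParams:
    """Per-channel population mean/std over all training pixels.

    Degenerate (constant) channels get sigma clamped to 1 so normalisation
    stays well-defined.
    """
    tensors = list(tensors)
    if len(tensors) < 2:
        raise ValueError("need at least 2 tensors to fit a normaliser")
    stacked = np.stack([t.channels for t in tensors])  # (n, 4, h, w)
    mu = stacked.mean(axis=(0, 2, 3))
    sigma = stacked.std(axis=(0, 2, 3))  # population std
    sigma = np.where(sigma > 0, sigma, 1.0)
    return NormalizerParams(mu=tuple(mu), sigma=tuple(sigma), fitted_on=fitted_on)


def apply_normalizer(tensor: BandeletTensor, params: NormalizerParams) -> BandeletTensor:
    """Channel-wise z-score ``(x - mu) / sigma``; refuses double application."""
    if tensor.normalised:
        raise ValueError("tensor is already normalised")
    mu = np.asarray(params.mu)[:, None, None]
    sigma = np.asarray(params.sigma)[:, None, None]
    return BandeletTensor(
        channels=(tensor.channels - mu) / sigma,
        normalised=True,
        source_id=tensor.source_id,
    )


def save_tensors(path, tensors, labels) -> None:
    """Write tensors to a named-array archive plus an embedded manifest.

    The manifest maps each array name to ``(source_id, label, normalised)``
    so the provenance chain image -> tensor -> label survives the round
    trip.
    """
    tensors = list(tensors)
    labels = list(labels)
    if len(tensors) != len(labels):
        raise ValueError("tensors and labels must have equal length")
    arrays = {}
    manifest = []
    for i, (t, y) in enumerate(zip(tensors, labels)):
        arrays[f"tensor_{i}"] = t.channels
        manifest.append([f"tensor_{i}", t.source_id, str(int(y)),
                         "1" if t.normalised else "0"])
    arrays["manifest"] = np.array(manifest, dtype=str)
    np.savez(path, **arrays)


def load_tensors(path):
    """Inverse of :func:`save_tensors`; returns ``(tensors, labels)``."""
    with np.load(path, allow_pickle=False) as npz:
        tensors, labels = [], []
        for name, source_id, label, normalised in npz["manifest"]:
            tensors.append(BandeletTensor(
                channels=npz[str(name)],
                normalised=normalised == "1",
                source_id=str(source_id),
            ))
            labels.append(int(label))
    return tensors, labels
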