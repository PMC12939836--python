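"""Separable 2D discrete wavelet analysis and synthesis.

The multilevel 2D DWT splits an image into an approximation grid (LL, kept
only at the coarsest level) and, per level, three detail grids responding to
horizontal (LH), vertical (HL) and diagonal (HH) structure.  This is the
isotropic baseline that the geometry-adaptive bandelet machinery in
:mod:`bandelet.quadtree` improves on.

All transforms go through PyWavelets.  The default boundary mode is
``periodization``, under which orthonormal filters give exact energy
conservation (Parseval) and coefficient counts equal to pixel counts for
power-of-two shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = ["SubbandSet", "dwt2", "idwt2", "hard_threshold", "save_subbands", "load_subbands"]

DEFAULT_WAVELET = "db2"
DEFAULT_MODE = "periodization"


@dataclass
class SubbandSet:
    """Multilevel 2D DWT coefficients.

    ``details[j]`` holds the ``(LH, HL, HH)`` grids of level ``j + 1``
    (level 1 is the finest); ``ll`` is the coarsest approximation grid.
    """

    ll: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    wavelet_name: str
    original_shape: tuple[int, int]
    mode: str = DEFAULT_MODE

    @property
    def levels(self) -> int:
        return len(self.details)

    def detail_count(self) -> int:
        """Total number of detail coefficients across levels."""
        return sum(g.size for lvl in self.details for g in lvl)

    def copy(self) -> "SubbandSet":
        return SubbandSet(
            ll=self.ll.copy(),
            details=[tuple(g.copy() for g in lvl) for lvl in self.details],
            wavelet_name=self.wavelet_name,
            original_shape=self.original_shape,
            mode=self.mode,
        )


def _check_wavelet(name: str) -> pywt.Wavelet:
    try:
        w = pywt.Wavelet(name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {name!r}") from exc
    return w


def dwt2(
    image: np.ndarray,
    wavelet_name: str = DEFAULT_WAVELET,
    levels: int = 1,
    mode: str = DEFAULT_MODE,
) -> SubbandSet:
    """Multilevel separable 2D DWT of a greyscale image.

    Parameters
    ----------
    image:
        2D finite-valued array.
    wavelet_name:
        Name of an orthogonal PyWavelets filter pair (default ``db2``).
    levels:
        Decomposition depth; must satisfy ``1 <= levels <=
        floor(log2(min(shape)))``.
    mode:
        Boundary extension; ``periodization`` preserves counts and energy.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={image.ndim}")
    if image.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    max_levels = int(np.floor(np.log2(min(image.shape))))
    if not 1 <= levels <= max_levels:
        raise ValueError(
            f"levels={levels} out of range [1, {max_levels}] for shape {image.shape}"
        )
    wav = _check_wavelet(wavelet_name)
    coeffs = pywt.wavedec2(image, wav, mode=mode, level=levels)
    ll = coeffs[0]
    # pywt orders coarsest-to-finest; store finest-first.
    details = [tuple(np.asarray(g) for g in lvl) for lvl in reversed(coeffs[1:])]
    return SubbandSet(
        ll=np.asarray(ll),
        details=details,
        wavelet_name=wavelet_name,
        original_shape=image.shape,
        mode=mode,
    )


def idwt2(subbands: SubbandSet) -> np.ndarray:
    """Synthesis inverse of :func:`dwt2`; returns a grid of the original shape."""
    coeffs = [subbands.ll] + [tuple(lvl) for lvl in reversed(subbands.details)]
    # Validate per-level shape consistency before handing to pywt.
    for lvl in subbands.details:
        shapes = {g.shape for g in lvl}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent subband shapes within a level: {shapes}")
    rec = pywt.waverec2(coeffs, pywt.Wavelet(subbands.wavelet_name), mode=subbands.mode)
    h, w = subbands.original_shape
    if rec.shape[0] < h or rec.shape[1] < w:
        raise ValueError("subband shapes inconsistent with original_shape")
    return rec[:h, :w]


def hard_threshold(subbands: SubbandSet, T: float) -> tuple[SubbandSet, int]:
    """Zero all detail coefficients with ``|c| <= T``; LL untouched.

    A coefficient survives only under strict ``|c| > T`` — the same
    significance rule the quadtree cost uses — and the survivor count is
    returned alongside the thresholded set.
    """
    if T < 0:
        raise ValueError(f"threshold must be nonnegative, got {T}")
    out = subbands.copy()
    survivors = 0
    for j, lvl in enumerate(out.details):
        new_lvl = []
        for g in lvl:
            mask = np.abs(g) > T
            survivors += int(mask.sum())
            new_lvl.append(np.where(mask, g, 0.0))
        out.details[j] = tuple(new_lvl)
    return out, survivors


def save_subbands(path, subbands: SubbandSet) -> None:
    """Write a SubbandSet to a named-array ``.npz`` archive."""
    arrays = {"ll": subbands.ll}
    for j, (lh, hl, hh) in enumerate(subbands.details, start=1):
        arrays[f"lh{j}"] = lh
        arrays[f"hl{j}"] = hl
        arrays[f"hh{j}"] = hh
    header = np.array(
        [subbands.wavelet_name, subbands.mode, str(subbands.levels),
         str(subbands.original_shape[0]), str(subbands.original_shape[1])]
    )
    np.savez(path, header=header, **arrays)


def load_subbands(path) -> SubbandSet:
    with np.load(path, allow_pickle=False) as npz:
        header = npz["header"]
        wavelet_name, mode = str(header[0]), str(header[1])
        levels = int(header[2])
        shape = (int(header[3]), int(header[4]))
        details = [
            (npz[f"lh{j}"], npz[f"hl{j}"], npz[f"hh{j}"]) for j in range(1, levels + 1)
        ]
        return SubbandSet(
            ll=npz["ll"], details=details, wavelet_name=wavelet_name,
            original_shape=shape, mode=mode,
        )
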