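"""Per-block geometric flow: candidate directions and the warped ordering.

A block's geometric flow is a single slope c' describing the direction along
which intensity varies least; the associated unit tangent is
``tau = (1, c') / sqrt(1 + c'^2)``.  Instead of resampling the block along
that direction (which would break invertibility), the warp is realised as an
exact reordering of grid positions by the key ``x2 - c' * x1`` — a
permutation, hence losslessly invertible.

``NO_FLOW`` is the distinguished candidate meaning "no significant geometric
variation": the block is left in its raw separable-wavelet form.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "NO_FLOW",
    "FlowCandidate",
    "FlowDictionary",
    "build_dictionary",
    "flow_vector",
    "warp_order",
    "inverse_warp_order",
    "estimate_flow",
]


class _NoFlow:
    """Sentinel for blocks with no significant geometric variation."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NO_FLOW"


NO_FLOW = _NoFlow()


@dataclass(frozen=True)
class FlowCandidate:
    """One entry of the flow dictionary.

    ``slope`` is either a finite real c' or ``NO_FLOW``; ``tau`` is the unit
    tangent (absent for NO_FLOW); ``dictionary_index`` identifies the entry.
    """

    slope: object
    dictionary_index: int

    @property
    def is_flow(self) -> bool:
        return self.slope is not NO_FLOW

    @property
    def tau(self) -> np.ndarray:
        if not self.is_flow:
            raise ValueError("NO_FLOW has no direction")
        return flow_vector(self.slope)


@dataclass(frozen=True)
class FlowDictionary:
    """Finite search space of candidate slopes; entry 0 is always NO_FLOW."""

    entries: tuple[FlowCandidate, ...]

    @property
    def slopes(self) -> tuple[float, ...]:
        return tuple(e.slope for e in self.entries if e.is_flow)

    @property
    def geometry_bits(self) -> int:
        return max(1, int(np.ceil(np.log2(len(self.entries)))))

    def __len__(self) -> int:
        return len(self.entries)


def build_dictionary(n_directions: int = 16, max_slope: float = 2.0) -> FlowDictionary:
    """Uniform slope dictionary: NO_FLOW + n_directions slopes in
    [-max_slope, +max_slope] + a forced 0 (deduplicated).

    The slope multiset is symmetric about 0 by construction.
    """
    if n_directions < 2 or n_directions % 2 != 0:
        raise ValueError(f"n_directions must be an even integer >= 2, got {n_directions}")
    if max_slope <= 0:
        raise ValueError(f"max_slope must be positive, got {max_slope}")
    # Uniform grid on [-max_slope, max_slope]; the positive half mirrors the
    # negative half exactly so the multiset is closed under negation.
    neg_half = [float(s) for s in np.linspace(-max_slope, 0.0, n_directions // 2,
                                              endpoint=False)]
    slopes = neg_half + [-s for s in reversed(neg_half)]
    if not any(s == 0.0 for s in slopes):
        slopes.append(0.0)
    entries = [FlowCandidate(NO_FLOW, 0)]
    entries += [FlowCandidate(float(s), i + 1) for i, s in enumerate(slopes)]
    return FlowDictionary(tuple(entries))


def flow_vector(slope: float) -> np.ndarray:
    """Unit tangent ``(1, c') / sqrt(1 + c'^2)`` of a finite slope."""
    if slope is NO_FLOW:
        raise ValueError("NO_FLOW defines no direction")
    slope = float(slope)
    if not np.isfinite(slope):
        raise ValueError(f"slope must be finite, got {slope}")
    return np.array([1.0, slope]) / np.sqrt(1.0 + slope * slope)


@lru_cache(maxsize=4096)
def _warp_order_cached(h: int, w: int, slope: float) -> tuple[np.ndarray, np.ndarray]:
    # Positions (x1, x2) with x1 along axis 0; key = x2 - slope * x1,
    # ties broken by ascending x1.  lexsort: last key is primary.
    x1, x2 = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    x1 = x1.ravel()
    x2 = x2.ravel()
    key = x2 - slope * x1
    perm = np.lexsort((x1, key))
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    perm.setflags(write=False)
    inv.setflags(write=False)
    return perm, inv


def warp_order(block_shape: tuple[int, int], slope: float) -> np.ndarray:
    """Permutation of the flattened (row-major) grid positions of a block,
    sorted by the warped key ``x2 - slope * x1``.

    Returns indices such that ``block.ravel()[perm]`` traverses positions in
    warped order.  Being a permutation, the ordering is exactly invertible.
    """
    h, w = block_shape
    if h < 1 or w < 1:
        raise ValueError(f"empty block shape {block_shape}")
    if slope is NO_FLOW or not np.isfinite(float(slope)):
        raise ValueError(f"slope must be finite, got {slope!r}")
    return _warp_order_cached(int(h), int(w), float(slope))[0]


def inverse_warp_order(block_shape: tuple[int, int], slope: float) -> np.ndarray:
    """Inverse permutation of :func:`warp_order`."""
    h, w = block_shape
    if h < 1 or w < 1:
        raise ValueError(f"empty block shape {block_shape}")
    return _warp_order_cached(int(h), int(w), float(slope))[1]


def estimate_flow(block, dictionary: FlowDictionary, T: float, lam: float,
                  wavelet_name: str = "db2"):
    """Exhaustive Lagrangian search over the dictionary.

    Every entry is scored with :func:`bandelet.quadtree.block_cost` (NO_FLOW
    scores the raw block, a slope scores the bandeletised block) and the
    argmin is returned as ``(FlowCandidate, cost)``.  Ties favour NO_FLOW,
    then the smaller ``|slope|``, then the negative sign — the simplest
    geometric model wins, and the result is deterministic.
    """
    from .quadtree import estimate_flow_impl  # local import; avoids a cycle

    if len(dictionary) == 0:
        raise ValueError("empty flow dictionary")
    return estimate_flow_impl(block, dictionary, T, lam, wavelet_name)
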