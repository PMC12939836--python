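"""Quadtree best-basis bandelet transform: forward, cost model, exact inverse.

The transform operates on wavelet detail subbands (a second-generation
construction).  Each subband is zero-padded to a dyadic square and covered by
a quadtree.  For every node the Lagrangian cost of encoding the block
directly — under the best flow candidate — is compared with the cumulative
cost of its four quadrants plus a ``lambda * T**2`` subdivision overhead:

    L_direct(S) = min over flow candidates of block_cost(S, flow)
    L_tilde(S)  = L0(S1) + L0(S2) + L0(S3) + L0(S4) + lambda * T**2
    L0(S)       = min(L_direct(S), L_tilde(S))

where ``block_cost`` is distortion after hard thresholding at T plus
``lambda * T**2`` times a significance budget: one unit per surviving
coefficient (R_B) plus the geometry side-information (R_G — the dictionary
index width for a flowed block, 1 for NO_FLOW).  Bottom-up dynamic
programming over the dyadic tree yields the global optimum.

Bandeletisation of a flowed leaf reorders the block along the warped key
``x2 - c' * x1`` and applies a full-depth orthogonal 1D DWT to the warped
sequence; anisotropic regularity along the flow becomes coefficient
sparsity.  Both the reordering (a permutation) and the 1D DWT (orthogonal,
periodised) are exactly invertible, so the whole transform reconstructs the
source image to machine precision when nothing is thresholded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pywt

from .flow import (
    NO_FLOW,
    FlowCandidate,
    FlowDictionary,
    build_dictionary,
    inverse_warp_order,
    warp_order,
)
from .wavelet import SubbandSet, dwt2, idwt2

__all__ = [
    "TransformParams",
    "QuadtreeNode",
    "BandeletRepresentation",
    "bandeletize_block",
    "inverse_bandeletize_block",
    "block_cost",
    "best_quadtree",
    "forward_bandelet",
    "inverse_bandelet",
    "save_representation",
    "load_representation",
]

DIRECT = "DIRECT"
SUBDIVIDE = "SUBDIVIDE"


@dataclass(frozen=True)
class TransformParams:
    """Parameters of the full bandelet transform.

    ``T`` is the significance threshold on the 8-bit intensity scale (images
    are 0–255 floats); ``lam`` the Lagrangian multiplier trading distortion
    against the significance budget; ``min_block`` the smallest quadtree
    leaf side.
    """

    wavelet_name: str = "db2"
    levels: int = 2
    T: float = 30.0
    lam: float = 4.0
    n_directions: int = 16
    max_slope: float = 2.0
    min_block: int = 4

    def dictionary(self) -> FlowDictionary:
        return build_dictionary(self.n_directions, self.max_slope)


@dataclass
class QuadtreeNode:
    """One node of the best-basis quadtree over a (padded) subband."""

    region: tuple[int, int, int, int]  # (x1_off, x2_off, h, w), half-open
    decision: str
    flow: FlowCandidate | None = None            # DIRECT nodes only
    children: list["QuadtreeNode"] | None = None  # SUBDIVIDE: S1..S4 raster order
    L_direct: float = 0.0
    L_tilde: float = np.inf
    L0: float = 0.0

    def leaves(self):
        if self.decision == DIRECT:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()


def _full_depth(n: int) -> int:
    """Depth of the 1D periodised DWT on a length-n sequence: as deep as the
    dyadic structure of n allows (full depth log2(n) for powers of two)."""
    depth = 0
    while n % 2 == 0 and n > 1:
        n //= 2
        depth += 1
    return depth


@lru_cache(maxsize=64)
def _wavelet(name: str) -> pywt.Wavelet:
    return pywt.Wavelet(name)


def _dwt1_full(seq: np.ndarray, wavelet_name: str) -> np.ndarray:
    level = _full_depth(seq.size)
    if level == 0:
        return seq.copy()
    with warnings.catch_warnings():
        # Full-depth periodised decomposition is orthogonal and exactly
        # invertible at any depth; pywt warns about boundary effects only.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(seq, _wavelet(wavelet_name), mode="periodization", level=level)
    return np.concatenate(coeffs)


def _idwt1_full(vec: np.ndarray, wavelet_name: str) -> np.ndarray:
    n = vec.size
    level = _full_depth(n)
    if level == 0:
        return vec.copy()
    # Rebuild the wavedec split structure from the length alone: the
    # periodised transform halves the length at each level.
    lengths = []
    m = n
    for _ in range(level):
        lengths.append(m // 2)
        m //= 2
    lengths.append(m)  # coarsest approximation
    parts = []
    pos = 0
    for ln in [lengths[-1]] + lengths[-2::-1]:
        parts.append(vec[pos:pos + ln])
        pos += ln
    return pywt.waverec(parts, _wavelet(wavelet_name), mode="periodization")


def bandeletize_block(
    block: np.ndarray, flow: FlowCandidate, wavelet_name: str = "db2"
) -> np.ndarray:
    """Warp a block along its flow and take a full-depth 1D orthogonal DWT.

    The block is flattened by ``warp_order(shape, slope)`` and the warped
    sequence is transformed; length is preserved.  Raises for ``NO_FLOW``
    (such blocks are simply left untouched by the caller).
    """
    if flow is None or not flow.is_flow:
        raise ValueError("bandeletisation requires a flow; NO_FLOW blocks stay raw")
    block = np.asarray(block, dtype=float)
    perm = warp_order(block.shape, flow.slope)
    return _dwt1_full(block.ravel()[perm], wavelet_name)


def inverse_bandeletize_block(
    coeffs: np.ndarray,
    flow: FlowCandidate,
    block_shape: tuple[int, int],
    wavelet_name: str = "db2",
) -> np.ndarray:
    """Exact inverse of :func:`bandeletize_block`."""
    if flow is None or not flow.is_flow:
        raise ValueError("NO_FLOW blocks are stored raw; nothing to invert")
    h, w = block_shape
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size != h * w:
        raise ValueError(f"coefficient length {coeffs.size} != block size {h * w}")
    seq = _idwt1_full(coeffs, wavelet_name)[: h * w]
    inv = inverse_warp_order(block_shape, flow.slope)
    # seq is in warped order; inv maps warped rank -> raster position ordering
    flat = seq[inv]
    return flat.reshape(h, w)


def block_cost(
    block: np.ndarray,
    flow: FlowCandidate,
    T: float,
    lam: float,
    geometry_bits: int,
    wavelet_name: str = "db2",
) -> float:
    """Lagrangian cost of encoding one block under one flow candidate.

    distortion + lam * T**2 * (R_G + R_B), where distortion is the squared
    error left by hard thresholding at T (equal to the pixel-domain error by
    orthonormality), R_B counts coefficients with ``|c| > T`` and R_G is
    ``geometry_bits`` for a flowed block, 1 for NO_FLOW.
    """
    if T < 0:
        raise ValueError(f"threshold must be nonnegative, got {T}")
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    block = np.asarray(block, dtype=float)
    if flow is not None and flow.is_flow:
        coeffs = bandeletize_block(block, flow, wavelet_name)
        r_g = geometry_bits
    else:
        coeffs = block.ravel()
        r_g = 1
    discarded = np.abs(coeffs) <= T
    distortion = float(np.sum(coeffs[discarded] ** 2))
    r_b = int(coeffs.size - discarded.sum())
    return distortion + lam * T * T * (r_g + r_b)


def best_quadtree(
    subband: np.ndarray,
    T: float,
    lam: float,
    dictionary: FlowDictionary,
    min_block: int = 4,
    wavelet_name: str = "db2",
) -> QuadtreeNode:
    """Globally optimal quadtree over a dyadic-square subband.

    Bottom-up dynamic programming: each node takes the cheaper of DIRECT
    encoding (with its best flow) and subdivision (children cost plus the
    ``lam * T**2`` overhead); ties go to DIRECT.  Nodes at ``min_block`` are
    forced DIRECT.
    """
    subband = np.asarray(subband, dtype=float)
    h, w = subband.shape if subband.ndim == 2 else (0, 0)
    if subband.ndim != 2 or h != w or h < 1 or (h & (h - 1)) != 0:
        raise ValueError(
            f"subband must be a square with power-of-two side (got shape "
            f"{subband.shape}); pad upstream with pad_to_dyadic_square"
        )
    if min_block < 2:
        raise ValueError(f"min_block must be >= 2, got {min_block}")
    if h < min_block:
        raise ValueError(f"subband side {h} below min_block {min_block}")

    def build(x1: int, x2: int, size: int) -> QuadtreeNode:
        block = subband[x1:x1 + size, x2:x2 + size]
        flow, l_direct = estimate_flow_on(block)
        node = QuadtreeNode(
            region=(x1, x2, size, size), decision=DIRECT, flow=flow,
            L_direct=l_direct, L0=l_direct,
        )
        if size // 2 >= min_block:
            half = size // 2
            children = [
                build(x1, x2, half),
                build(x1, x2 + half, half),
                build(x1 + half, x2, half),
                build(x1 + half, x2 + half, half),
            ]
            l_tilde = sum(c.L0 for c in children) + lam * T * T
            node.L_tilde = l_tilde
            if l_tilde < l_direct:  # tie -> DIRECT
                node.decision = SUBDIVIDE
                node.children = children
                node.flow = None
                node.L0 = l_tilde
        return node

    def estimate_flow_on(block):
        return estimate_flow_impl(block, dictionary, T, lam, wavelet_name)

    return build(0, 0, h)


def estimate_flow_impl(block, dictionary, T, lam, wavelet_name):
    """estimate_flow with an explicit bandeletisation wavelet."""
    bits = dictionary.geometry_bits

    def preference(e: FlowCandidate):
        if not e.is_flow:
            return (0, 0.0, 0)
        return (1, abs(e.slope), 0 if e.slope < 0 else 1)

    best = None
    best_cost = np.inf
    for entry in sorted(dictionary.entries, key=preference):
        cost = block_cost(block, entry, T, lam, bits, wavelet_name)
        if cost < best_cost:
            best, best_cost = entry, cost
    return best, best_cost


def pad_to_dyadic_square(grid: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad a grid to the smallest enclosing power-of-two square."""
    h, w = grid.shape
    side = 1 << int(np.ceil(np.log2(max(h, w, 1))))
    side = max(side, 1)
    out = np.zeros((side, side), dtype=float)
    out[:h, :w] = grid
    return out, (h, w)


@dataclass
class BandeletRepresentation:
    """Full bandelet representation of an image.

    One quadtree per detail subband per level (finest level first, each level
    a ``(LH, HL, HH)`` triple); coarsest LL kept raw.  ``leaf_coeffs`` maps
    ``(level_index, orientation_index, region)`` to the leaf's coefficient
    vector — bandeletised when the leaf carries a flow, raw otherwise.
    """

    params: TransformParams
    ll: np.ndarray
    original_shape: tuple[int, int]
    subband_shapes: list[tuple[int, int]]       # unpadded detail shape per level
    trees: list[tuple[QuadtreeNode, QuadtreeNode, QuadtreeNode]]
    leaf_coeffs: dict = field(default_factory=dict)
    total_cost: float = 0.0
    significant_count: int = 0

    @property
    def levels(self) -> int:
        return len(self.trees)

    def coefficient_count(self) -> int:
        return sum(v.size for v in self.leaf_coeffs.values())


def forward_bandelet(image: np.ndarray, params: TransformParams) -> BandeletRepresentation:
    """Forward bandelet transform of a greyscale image.

    2D DWT, then per detail subband: pad to a dyadic square, run the
    best-basis quadtree search, and bandeletise every flowed leaf.  Records
    the summed optimal Lagrangian cost and the number of significant
    (``|c| > T``) detail coefficients.
    """
    subbands = dwt2(image, params.wavelet_name, params.levels)
    dictionary = params.dictionary()
    trees = []
    leaf_coeffs = {}
    shapes = []
    total_cost = 0.0
    significant = 0
    for li, level in enumerate(subbands.details):
        level_trees = []
        for oi, grid in enumerate(level):
            padded, orig_shape = pad_to_dyadic_square(grid)
            tree = best_quadtree(
                padded, params.T, params.lam, dictionary,
                min_block=min(params.min_block, padded.shape[0]),
                wavelet_name=params.wavelet_name,
            )
            total_cost += tree.L0
            for leaf in tree.leaves():
                x1, x2, h, w = leaf.region
                block = padded[x1:x1 + h, x2:x2 + w]
                if leaf.flow is not None and leaf.flow.is_flow:
                    vec = bandeletize_block(block, leaf.flow, params.wavelet_name)
                else:
                    vec = block.ravel().copy()
                leaf_coeffs[(li, oi, leaf.region)] = vec
                significant += int(np.count_nonzero(np.abs(vec) > params.T))
            level_trees.append(tree)
            if oi == 0:
                shapes.append(orig_shape)
        trees.append(tuple(level_trees))
    return BandeletRepresentation(
        params=params,
        ll=subbands.ll.copy(),
        original_shape=subbands.original_shape,
        subband_shapes=shapes,
        trees=trees,
        leaf_coeffs=leaf_coeffs,
        total_cost=total_cost,
        significant_count=significant,
    )


def _rebuild_subband(rep: BandeletRepresentation, li: int, oi: int) -> np.ndarray:
    tree = rep.trees[li][oi]
    side = tree.region[2]
    padded = np.zeros((side, side))
    for leaf in tree.leaves():
        x1, x2, h, w = leaf.region
        vec = rep.leaf_coeffs[(li, oi, leaf.region)]
        if vec.size != h * w:
            raise ValueError("leaf coefficient length mismatch")
        if leaf.flow is not None and leaf.flow.is_flow:
            block = inverse_bandeletize_block(vec, leaf.flow, (h, w), rep.params.wavelet_name)
        else:
            block = vec.reshape(h, w)
        padded[x1:x1 + h, x2:x2 + w] = block
    h, w = rep.subband_shapes[li]
    return padded[:h, :w]


def inverse_bandelet(rep: BandeletRepresentation) -> np.ndarray:
    """Exact inverse of :func:`forward_bandelet`."""
    details = []
    for li in range(rep.levels):
        details.append(tuple(_rebuild_subband(rep, li, oi) for oi in range(3)))
    subbands = SubbandSet(
        ll=rep.ll,
        details=details,
        wavelet_name=rep.params.wavelet_name,
        original_shape=rep.original_shape,
    )
    return idwt2(subbands)


def threshold_representation(rep: BandeletRepresentation, T: float | None = None):
    """Hard-threshold all leaf coefficients at T (default: the transform's T).

    Returns ``(thresholded representation, survivor count)``; the coarsest
    LL is untouched, mirroring :func:`bandelet.wavelet.hard_threshold`.
    """
    if T is None:
        T = rep.params.T
    if T < 0:
        raise ValueError("threshold must be nonnegative")
    out = BandeletRepresentation(
        params=rep.params, ll=rep.ll.copy(), original_shape=rep.original_shape,
        subband_shapes=list(rep.subband_shapes), trees=rep.trees,
        leaf_coeffs={}, total_cost=rep.total_cost,
    )
    survivors = 0
    for key, vec in rep.leaf_coeffs.items():
        mask = np.abs(vec) > T
        survivors += int(mask.sum())
        out.leaf_coeffs[key] = np.where(mask, vec, 0.0)
    out.significant_count = survivors
    return out, survivors


# ---------------------------------------------------------------------------
# Serialisation: flat tree table + one coefficient vector per leaf.

def _flatten_tree(node: QuadtreeNode, rows: list, parent: int = -1) -> None:
    idx = len(rows)
    flow_idx = -1
    if node.decision == DIRECT and node.flow is not None:
        flow_idx = node.flow.dictionary_index
    rows.append(
        [parent, *node.region, 1 if node.decision == SUBDIVIDE else 0,
         flow_idx, node.L_direct, node.L_tilde, node.L0]
    )
    if node.children:
        for c in node.children:
            _flatten_tree(c, rows, idx)


def _unflatten_tree(rows: np.ndarray, dictionary: FlowDictionary) -> QuadtreeNode:
    nodes = []
    for row in rows:
        parent = int(row[0])
        region = tuple(int(v) for v in row[1:5])
        subdivide = bool(row[5])
        flow_idx = int(row[6])
        node = QuadtreeNode(
            region=region,
            decision=SUBDIVIDE if subdivide else DIRECT,
            flow=None if flow_idx < 0 else dictionary.entries[flow_idx],
            L_direct=float(row[7]), L_tilde=float(row[8]), L0=float(row[9]),
        )
        if subdivide:
            node.children = []
        nodes.append(node)
        if parent >= 0:
            nodes[parent].children.append(node)
    return nodes[0]


def save_representation(path, rep: BandeletRepresentation) -> None:
    """Write a BandeletRepresentation to a named-array ``.npz`` archive,
    bit-exact on round trip."""
    p = rep.params
    arrays = {
        "ll": rep.ll,
        "header": np.array(
            [p.wavelet_name, str(p.levels), repr(p.T), repr(p.lam),
             str(p.n_directions), repr(p.max_slope), str(p.min_block),
             str(rep.original_shape[0]), str(rep.original_shape[1]),
             repr(rep.total_cost), str(rep.significant_count)]
        ),
        "subband_shapes": np.array(rep.subband_shapes, dtype=np.int64),
    }
    for li, level in enumerate(rep.trees):
        for oi, tree in enumerate(level):
            rows: list = []
            _flatten_tree(tree, rows)
            arrays[f"tree_{li}_{oi}"] = np.array(rows, dtype=float)
    for i, (key, vec) in enumerate(sorted(rep.leaf_coeffs.items())):
        li, oi, region = key
        arrays[f"leaf_{i}_meta"] = np.array([li, oi, *region], dtype=np.int64)
        arrays[f"leaf_{i}_vec"] = vec
    np.savez(path, **arrays)


def load_representation(path) -> BandeletRepresentation:
    with np.load(path, allow_pickle=False) as npz:
        h = npz["header"]
        params = TransformParams(
            wavelet_name=str(h[0]), levels=int(h[1]), T=float(h[2]),
            lam=float(h[3]), n_directions=int(h[4]), max_slope=float(h[5]),
            min_block=int(h[6]),
        )
        dictionary = params.dictionary()
        shapes = [tuple(int(v) for v in row) for row in npz["subband_shapes"]]
        trees = []
        for li in range(params.levels):
            trees.append(tuple(
                _unflatten_tree(npz[f"tree_{li}_{oi}"], dictionary) for oi in range(3)
            ))
        leaf_coeffs = {}
        i = 0
        while f"leaf_{i}_meta" in npz:
            meta = npz[f"leaf_{i}_meta"]
            key = (int(meta[0]), int(meta[1]), tuple(int(v) for v in meta[2:6]))
            leaf_coeffs[key] = npz[f"leaf_{i}_vec"]
            i += 1
        rep = BandeletRepresentation(
            params=params, ll=npz["ll"],
            original_shape=(int(h[7]), int(h[8])),
            subband_shapes=shapes, trees=trees, leaf_coeffs=leaf_coeffs,
            total_cost=float(h[9]), significant_count=int(h[10]),
        )
        return rep
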