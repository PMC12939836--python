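"""Independent brute-force oracles for the transform tests.

These deliberately re-derive the warped ordering, the leaf cost and the
quadtree optimum from first principles (sorting positions, explicit
enumeration of every admissible tree) so they share no code path with the
package's dynamic-programming implementation.
"""

import itertools

import numpy as np
import pywt


def oracle_warp_sequence(block: np.ndarray, slope: float) -> np.ndarray:
    """Block values sorted by (x2 - slope*x1, x1) via plain Python sorting."""
    h, w = block.shape
    positions = [(i, j) for i in range(h) for j in range(w)]
    positions.sort(key=lambda p: (p[1] - slope * p[0], p[0]))
    return np.array([block[i, j] for i, j in positions], dtype=float)


def oracle_dwt1(seq: np.ndarray, wavelet: str) -> np.ndarray:
    n = seq.size
    level = 0
    m = n
    while m % 2 == 0 and m > 1:
        m //= 2
        level += 1
    if level == 0:
        return seq.copy()
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(seq, wavelet, mode="periodization", level=level)
    return np.concatenate(coeffs)


def oracle_leaf_cost(block: np.ndarray, slope, T: float, lam: float,
                     bits: int, wavelet: str) -> float:
    """Cost of one (block, candidate) pair, recomputed from the definition."""
    if slope is None:  # NO_FLOW
        coeffs = np.asarray(block, dtype=float).ravel()
        r_g = 1
    else:
        coeffs = oracle_dwt1(oracle_warp_sequence(block, slope), wavelet)
        r_g = bits
    kept = np.abs(coeffs) > T
    distortion = float(np.sum(coeffs[~kept] ** 2))
    return distortion + lam * T * T * (r_g + int(kept.sum()))


def oracle_best_leaf_cost(block, slopes, T, lam, bits, wavelet):
    """Brute-force argmin over NO_FLOW + every slope, with the NO_FLOW <
    smaller |slope| < negative-sign preference on exact ties."""
    candidates = [(None, oracle_leaf_cost(block, None, T, lam, bits, wavelet))]
    for s in slopes:
        candidates.append((s, oracle_leaf_cost(block, s, T, lam, bits, wavelet)))

    def rank(item):
        s, cost = item
        if s is None:
            return (cost, 0, 0.0, 0)
        return (cost, 1, abs(s), 0 if s < 0 else 1)

    return min(candidates, key=rank)


def oracle_quadtree_l0(subband: np.ndarray, T: float, lam: float, slopes,
                       bits: int, min_block: int, wavelet: str) -> float:
    """Minimum Lagrangian cost over ALL admissible quadtrees, enumerated
    explicitly (exponential, no memoisation)."""

    def enumerate_costs(x1, x2, size):
        block = subband[x1:x1 + size, x2:x2 + size]
        _, direct = oracle_best_leaf_cost(block, slopes, T, lam, bits, wavelet)
        costs = [direct]
        half = size // 2
        if half >= min_block:
            child_costs = [
                enumerate_costs(x1, x2, half),
                enumerate_costs(x1, x2 + half, half),
                enumerate_costs(x1 + half, x2, half),
                enumerate_costs(x1 + half, x2 + half, half),
            ]
            for combo in itertools.product(*child_costs):
                costs.append(sum(combo) + lam * T * T)
        return costs

    return min(enumerate_costs(0, 0, subband.shape[0]))
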