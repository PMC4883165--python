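"""Independent brute-force oracles used to pin the implementation.

These deliberately re-derive results from first principles (pixel-by-pixel
set enumeration, exhaustive threshold search) and share no code with the
package internals they check.
"""

from itertools import combinations

import numpy as np


def se_offsets(window, origin):
    return [
        (r - origin[0], c - origin[1])
        for r in range(window.shape[0])
        for c in range(window.shape[1])
        if window[r, c]
    ]


def erode_enum(mask, window, origin):
    """Set-definition erosion: pixel kept iff the translated SE fits in B."""
    offs = se_offsets(window, origin)
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for x in range(h):
        for y in range(w):
            out[x, y] = all(
                0 <= x + dr < h and 0 <= y + dc < w and mask[x + dr, y + dc]
                for dr, dc in offs
            )
    return out


def dilate_enum(mask, window, origin):
    """Set-definition dilation: pixel set iff the translated SE meets B."""
    offs = se_offsets(window, origin)
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for x in range(h):
        for y in range(w):
            out[x, y] = any(
                0 <= x + dr < h and 0 <= y + dc < w and mask[x + dr, y + dc]
                for dr, dc in offs
            )
    return out


def open_enum(mask, window, origin):
    return dilate_enum(erode_enum(mask, window, origin), window, origin)


def close_enum(mask, window, origin):
    return erode_enum(dilate_enum(mask, window, origin), window, origin)


def _partition_value(p, centers, cuts, n_bins):
    """Sum of p_c * m_c^2 over the classes delimited by the cut indices.

    Class mass and first moment come from cumulative sums so that cut
    tuples describing the same partition (cuts shifted across empty bins)
    evaluate to bitwise-identical values, making the lexicographic
    tie-break well defined under floating point.
    """
    P = np.concatenate(([0.0], np.cumsum(p)))
    Q = np.concatenate(([0.0], np.cumsum(p * centers)))
    bounds = [-1, *cuts, n_bins - 1]
    total = 0.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        pc = P[hi + 1] - P[lo + 1]
        if pc > 0:
            mc = (Q[hi + 1] - Q[lo + 1]) / pc
            total += pc * mc * mc
    return total


def multi_otsu_brute_force(p, centers, k):
    """Exhaustive search over all threshold tuples; first strict maximum wins
    (lexicographically smallest tie-break)."""
    n_bins = len(p)
    best_val = -np.inf
    best_cuts = None
    for cuts in combinations(range(n_bins - 1), k):
        val = _partition_value(p, centers, cuts, n_bins)
        if val > best_val:
            best_val = val
            best_cuts = cuts
    return best_cuts, best_val


def between_class_variance(p, centers, cuts):
    """Sum of p_c (m_c - m_I)^2 — the criterion on its original scale."""
    n_bins = len(p)
    m_total = (p * centers).sum()
    bounds = [-1, *cuts, n_bins - 1]
    total = 0.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        pc = p[lo + 1 : hi + 1].sum()
        if pc > 0:
            mc = (p[lo + 1 : hi + 1] * centers[lo + 1 : hi + 1]).sum() / pc
            total += pc * (mc - m_total) ** 2
    return total


def within_class_variance(p, centers, cuts):
    """Sum of p_c * Var_c — complements the between-class term."""
    n_bins = len(p)
    bounds = [-1, *cuts, n_bins - 1]
    total = 0.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        pc = p[lo + 1 : hi + 1].sum()
        if pc > 0:
            sel = slice(lo + 1, hi + 1)
            mc = (p[sel] * centers[sel]).sum() / pc
            var = (p[sel] * (centers[sel] - mc) ** 2).sum() / pc
            total += pc * var
    return total
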