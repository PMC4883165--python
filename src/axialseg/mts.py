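"""Histogram thresholding: single and multi-level Otsu segmentation.

The image histogram is treated as a discrete probability density
``p_i = f_i / N`` over ``J`` equal-width bins on ``[0, 1]``.  The single
Otsu threshold maximises the between-class variance

    sigma_B^2(d) = p_r1(d) [m_r1(d) - m_I]^2 + p_r2(d) [m_r2(d) - m_I]^2,

where region 1 covers bins ``0..d`` and region 2 bins ``d+1..J-1`` with
probabilities and means given by the usual cumulative sums; maximising
between-class variance is equivalent to minimising the within-class
(intra-class) variance because the two sum to the total variance.

``multi_otsu`` generalises this to ``k`` thresholds / ``k+1`` classes and
finds the *exact* maximiser of the between-class variance sum by dynamic
programming over prefix moments (``O(k * J^2)``), not by the usual iterative
heuristics.  Ties (which occur on runs of empty bins) are broken toward the
lexicographically smallest threshold tuple.

Tumor extraction takes the top intensity class — brain tissue is
mid-intensity while tumor is hyperintense on the stripped slice — and
removes residual speckle with a 3x3 average (majority) filter.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .io_formats import BinaryMask, GrayImage

__all__ = [
    "DegenerateInputError",
    "Histogram",
    "ThresholdSet",
    "TumorResult",
    "build_histogram",
    "otsu_threshold",
    "multi_otsu",
    "segment_tumor",
]


class DegenerateInputError(ValueError):
    """Raised when a histogram has too few occupied bins to threshold."""


@dataclasses.dataclass(frozen=True)
class Histogram:
    """A discrete intensity pdf over equal-width bins on [0, 1]."""

    p: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        if p.ndim != 1 or p.size < 2:
            raise ValueError("histogram needs at least 2 bins")
        if edges.shape != (p.size + 1,):
            raise ValueError("bin_edges must have length J + 1")
        if np.any(p < 0):
            raise ValueError("bin probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("bin probabilities must sum to 1")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "bin_edges", edges)

    @property
    def n_bins(self) -> int:
        return self.p.size

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_nonempty(self) -> int:
        return int(np.count_nonzero(self.p))


@dataclasses.dataclass(frozen=True)
class ThresholdSet:
    """Ordered Otsu thresholds with the achieved between-class variance.

    ``thresholds[c]`` is the upper bin edge of class ``c``; ``indices[c]``
    is the index of the last bin in class ``c``.
    """

    thresholds: Tuple[float, ...]
    indices: Tuple[int, ...]
    k: int
    criterion_value: float

    def __post_init__(self) -> None:
        if len(self.thresholds) != self.k or len(self.indices) != self.k:
            raise ValueError("expected k thresholds and k indices")
        t = np.asarray(self.thresholds)
        if self.k and np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")


@dataclasses.dataclass(frozen=True)
class TumorResult:
    """Tumor mask plus the pre-denoise map and the thresholds that produced it."""

    tumor_mask: BinaryMask
    raw_mask: BinaryMask
    thresholds: ThresholdSet


def build_histogram(
    image: GrayImage, mask: Optional[BinaryMask] = None, bins: int = 256
) -> Histogram:
    """Histogram of (optionally masked) pixel intensities, Sum p_i = 1."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if mask is not None:
        if mask.shape != image.shape:
            raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
        vals = image.pixels[mask.pixels]
        if vals.size == 0:
            raise ValueError("mask selects no pixels")
    else:
        vals = image.pixels.ravel()
    counts, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    return Histogram(counts / vals.size, edges)


def _class_cost(hist: Histogram) -> np.ndarray:
    """cost[i, j] = p_c * m_c^2 for the class spanning bins i..j (0 if empty)."""
    J = hist.n_bins
    P = np.concatenate(([0.0], np.cumsum(hist.p)))
    Q = np.concatenate(([0.0], np.cumsum(hist.p * hist.centers)))
    i = np.arange(J)[:, None]
    j = np.arange(J)[None, :]
    s = P[j + 1] - P[i]
    m = Q[j + 1] - Q[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = np.where(s > 0, m * m / np.where(s > 0, s, 1.0), 0.0)
    return np.where(j >= i, cost, -np.inf)


def _optimal_cuts(hist: Histogram, k: int) -> Tuple[Tuple[int, ...], float]:
    """Exact DP over class boundaries; returns (cut indices d_1..d_k, Sum p_c m_c^2)."""
    J = hist.n_bins
    cost = _class_cost(hist)
    # vals[j]: best Sum p_c m_c^2 using the current number of classes on bins 0..j
    vals = cost[0, :].copy()
    cuts: List[Tuple[int, ...]] = [() for _ in range(J)]
    for _level in range(k):
        new_vals = np.full(J, -np.inf)
        new_cuts: List[Tuple[int, ...]] = [() for _ in range(J)]
        for j in range(_level + 1, J):
            # class boundary candidates: previous classes end at bin i-1,
            # the new class spans bins i..j
            i_lo, i_hi = _level + 1, j
            cand = vals[i_lo - 1 : i_hi] + cost[i_lo : i_hi + 1, j]
            m = cand.max()
            ties = np.flatnonzero(cand == m)
            best = min(cuts[i_lo - 1 + t] + (i_lo - 1 + t,) for t in ties)
            new_vals[j] = m
            new_cuts[j] = best
        vals, cuts = new_vals, new_cuts
    return cuts[J - 1], float(vals[J - 1])


def _between_class_variance(hist: Histogram, cut_indices: Sequence[int]) -> float:
    """Sum over classes of p_c (m_c - m_I)^2 for the given partition."""
    bounds = [-1, *cut_indices, hist.n_bins - 1]
    c = hist.centers
    m_total = float(np.sum(hist.p * c))
    total = 0.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        pc = float(hist.p[lo + 1 : hi + 1].sum())
        if pc > 0:
            mc = float(np.sum(hist.p[lo + 1 : hi + 1] * c[lo + 1 : hi + 1])) / pc
            total += pc * (mc - m_total) ** 2
    return total


def multi_otsu(hist: Histogram, k: int) -> ThresholdSet:
    """Exact k-threshold Otsu partition of a histogram.

    Maximises the (k+1)-class between-class variance sum; equivalent to the
    single-threshold criterion for ``k == 1``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if hist.n_nonempty < k + 1:
        raise DegenerateInputError(
            f"need at least {k + 1} nonempty bins for {k} thresholds, "
            f"got {hist.n_nonempty}"
        )
    cut_indices, _ = _optimal_cuts(hist, k)
    thresholds = tuple(float(hist.bin_edges[d + 1]) for d in cut_indices)
    return ThresholdSet(
        thresholds=thresholds,
        indices=tuple(int(d) for d in cut_indices),
        k=k,
        criterion_value=_between_class_variance(hist, cut_indices),
    )


def otsu_threshold(hist: Histogram) -> Tuple[float, float]:
    """Single Otsu threshold: (T on a bin edge, achieved criterion value)."""
    ts = multi_otsu(hist, 1)
    return ts.thresholds[0], ts.criterion_value


def segment_tumor(
    brain: "StripResult",  # noqa: F821 - forward ref, see axialseg.skullstrip
    k: int = 8,
    bins: int = 256,
    denoise: str = "mean",
) -> TumorResult:
    """Extract the tumor as the top multi-Otsu intensity class of the brain.

    The histogram is built over brain-mask pixels only; the raw tumor map is
    ``intensity >= T_k`` and speckle is removed with a 3x3 average filter
    followed by a 0.5 majority vote (or a 3x3 median when
    ``denoise="median"``).  The result never extends outside the brain mask.
    """
    if denoise not in ("mean", "median"):
        raise ValueError("denoise must be 'mean' or 'median'")
    if not brain.converged:
        warnings.warn(
            "segmenting a non-converged skull-strip result", stacklevel=2
        )
    mask = brain.brain_mask
    image = brain.brain_image
    hist = build_histogram(image, mask=mask, bins=bins)
    thresholds = multi_otsu(hist, k)
    t_top = thresholds.thresholds[-1]
    raw = (image.pixels >= t_top) & mask.pixels
    raw_mask = BinaryMask(raw, mask.spacing)
    if not raw.any():
        warnings.warn("no pixels above the top threshold; empty tumor mask", stacklevel=2)
        return TumorResult(raw_mask, raw_mask, thresholds)
    if denoise == "mean":
        smooth = ndimage.uniform_filter(raw.astype(np.float64), size=3, mode="constant")
        clean = smooth > 0.5
    else:
        clean = ndimage.median_filter(raw, size=3, mode="constant", cval=False)
    return TumorResult(BinaryMask(clean & mask.pixels, mask.spacing), raw_mask, thresholds)
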