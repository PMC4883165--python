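"""Adaptive iterative morphological skull stripping of a 2-D axial slice.

The algorithm exploits the subdural space — the dark gap between brain and
skull — as a separating contour:

1.  Binarise the slice with a single Otsu threshold; the result ``I`` marks
    skull + brain as foreground, with the subdural gap as an enclosed hole.
2.  Fill the holes of ``I`` to get the solid head ``F_I``; the exclusive-or
    ``I XOR F_I`` is exactly the enclosed background, i.e. the subdural
    contour around the brain.
3.  Iterate: dilate the contour with a square window, fill holes, erode
    with the *same* window, and keep the part inside ``F_I``.  While the
    contour has discontinuities the filling step cannot close the ring and
    the recovered area stays small; the window half-width grows by one
    pixel per iteration until the ring closes, the interior (the brain)
    fills in, and the extracted area exceeds an area threshold
    ``th = area_fraction * area(F_I)`` — the convergence criterion.

Slices whose subdural space is thin or broken simply need more iterations;
that adaptivity is the point of the algorithm.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .io_formats import BinaryMask, GrayImage
from .morphology import StructuringElement, dilate, erode, fill_holes, mask_xor
from .mts import DegenerateInputError, build_histogram, otsu_threshold

__all__ = [
    "StripConfig",
    "StripResult",
    "binarize_otsu",
    "subdural_contour",
    "strip_iterate",
    "skull_strip",
]


@dataclasses.dataclass(frozen=True)
class StripConfig:
    """Parameters of the iterative loop.

    ``area_fraction``: convergence threshold as a fraction of the filled
    head area (scale-invariant across image sizes).  ``initial_half_width``:
    starting square-window half-width (side = 2*hw + 1); the half-width
    grows by one per iteration.  ``keep_largest_component`` guards against
    disconnected debris in the candidate mask.
    """

    area_fraction: float = 0.4
    initial_half_width: int = 1
    max_iterations: int = 25
    keep_largest_component: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.area_fraction < 1.0:
            raise ValueError("area_fraction must be in (0, 1)")
        if self.initial_half_width < 1:
            raise ValueError("initial_half_width must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclasses.dataclass(frozen=True)
class StripResult:
    brain_mask: BinaryMask
    brain_image: GrayImage
    iterations_used: int
    area_trace: Tuple[int, ...]
    threshold_area: float
    converged: bool


def binarize_otsu(image: GrayImage, bins: int = 256) -> Tuple[BinaryMask, float]:
    """Otsu-binarise a slice: (mask of pixels above T, T)."""
    try:
        hist = build_histogram(image, bins=bins)
        t, _ = otsu_threshold(hist)
    except DegenerateInputError as exc:
        raise DegenerateInputError(f"cannot binarise: {exc}") from exc
    return BinaryMask(image.pixels > t, image.spacing), t


def subdural_contour(binarized: BinaryMask) -> Tuple[BinaryMask, BinaryMask]:
    """(filled head F_I, subdural contour = holes of the binarised slice)."""
    filled = fill_holes(binarized)
    contour = mask_xor(binarized, filled)
    return filled, contour


_EIGHT = ndimage.generate_binary_structure(2, 2)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n <= 1:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == sizes.argmax()


def strip_iterate(
    image: GrayImage,
    contour: BinaryMask,
    filled_head: BinaryMask,
    config: Optional[StripConfig] = None,
) -> StripResult:
    """Run the growing-window dilate/fill/erode loop until convergence."""
    cfg = config or StripConfig()
    if contour.area == 0:
        raise ValueError("no subdural space detected: the binarised slice has no holes")
    th = cfg.area_fraction * filled_head.area
    trace = []
    brain = contour
    converged = False
    iterations = 0
    for k in range(cfg.max_iterations):
        se = StructuringElement.square(cfg.initial_half_width + k)
        candidate = erode(fill_holes(dilate(contour, se)), se)
        candidate = BinaryMask(candidate.pixels & filled_head.pixels, image.spacing)
        if cfg.keep_largest_component and candidate.area:
            candidate = BinaryMask(_largest_component(candidate.pixels), image.spacing)
        trace.append(candidate.area)
        brain = candidate
        iterations = k + 1
        if candidate.area > th:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"skull stripping did not converge in {cfg.max_iterations} iterations "
            f"(last area {trace[-1]}, threshold {th:.0f})",
            stacklevel=2,
        )
    brain_image = GrayImage(image.pixels * brain.pixels, image.spacing)
    return StripResult(
        brain_mask=brain,
        brain_image=brain_image,
        iterations_used=iterations,
        area_trace=tuple(trace),
        threshold_area=float(th),
        converged=converged,
    )


def skull_strip(image: GrayImage, config: Optional[StripConfig] = None) -> StripResult:
    """Full pipeline stage: Otsu binarise, extract contour, iterate to the brain."""
    binarized, _ = binarize_otsu(image)
    filled, contour = subdural_contour(binarized)
    return strip_iterate(image, contour, filled, config)
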