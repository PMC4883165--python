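"""Binary mathematical morphology on masks.

Erosion, dilation, opening, closing, exclusive-or and hole filling — the
operator set the skull-stripping loop is built from.  Erosion and dilation
follow the set definitions directly: with ``S_xy`` the structuring element
translated so its origin sits at ``(x, y)``,

    erode(B, S)[x, y]  = 1  iff  S_xy is a subset of B,
    dilate(B, S)[x, y] = 1  iff  S_xy intersects B,

with everything outside the raster treated as background.  Opening and
closing are the usual compositions.  Hole filling uses a 4-connected
background flood from the border (equivalently 8-connected foreground),
which prevents diagonal leaks through one-pixel subdural gaps.

All operators are pure functions on :class:`~axialseg.io_formats.BinaryMask`.
"""

from __future__ import annotations

import dataclasses
from typing import Tuple

import numpy as np
from scipy import ndimage

from .io_formats import BinaryMask

__all__ = [
    "StructuringElement",
    "erode",
    "dilate",
    "opening",
    "closing",
    "mask_xor",
    "fill_holes",
]


@dataclasses.dataclass(frozen=True)
class StructuringElement:
    """A small binary window with an origin pixel.

    Use :meth:`square` or :meth:`disk` for the usual centered symmetric
    elements; arbitrary windows/origins are accepted for generality.
    """

    window: np.ndarray
    origin: Tuple[int, int]

    def __post_init__(self) -> None:
        win = np.asarray(self.window)
        if win.ndim != 2:
            raise ValueError("structuring element window must be 2-D")
        if win.dtype != bool:
            vals = np.unique(win)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("window values must be 0 or 1")
            win = win.astype(bool)
        if not win.any():
            raise ValueError("structuring element must contain at least one 1")
        r, c = (int(self.origin[0]), int(self.origin[1]))
        if not (0 <= r < win.shape[0] and 0 <= c < win.shape[1]):
            raise ValueError(f"origin {self.origin} outside window of shape {win.shape}")
        object.__setattr__(self, "window", win)
        object.__setattr__(self, "origin", (r, c))

    @classmethod
    def square(cls, half_width: int) -> "StructuringElement":
        """Centered all-ones square of side ``2*half_width + 1``."""
        if half_width < 0:
            raise ValueError("half_width must be >= 0")
        side = 2 * half_width + 1
        return cls(np.ones((side, side), dtype=bool), (half_width, half_width))

    @classmethod
    def disk(cls, radius: int) -> "StructuringElement":
        """Centered digital disk: pixels with r^2 + c^2 <= radius^2."""
        if radius < 0:
            raise ValueError("radius must be >= 0")
        rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        return cls(rr * rr + cc * cc <= radius * radius, (radius, radius))

    @property
    def offsets(self) -> np.ndarray:
        """(n, 2) array of (drow, dcol) offsets of the support, origin-relative."""
        return np.argwhere(self.window) - np.asarray(self.origin)

    def reflect(self) -> "StructuringElement":
        """The element reflected through its origin (offsets negated)."""
        win = self.window[::-1, ::-1].copy()
        r = self.window.shape[0] - 1 - self.origin[0]
        c = self.window.shape[1] - 1 - self.origin[1]
        return StructuringElement(win, (r, c))

    def _is_centered_square(self) -> bool:
        h, w = self.window.shape
        return (
            h == w
            and h % 2 == 1
            and self.origin == (h // 2, w // 2)
            and bool(self.window.all())
        )


def _shift_reduce(mask: np.ndarray, se: StructuringElement, require_all: bool) -> np.ndarray:
    """AND (erosion) or OR (dilation) of ``mask`` shifted by each SE offset."""
    offs = se.offsets
    pr = int(np.abs(offs[:, 0]).max(initial=0))
    pc = int(np.abs(offs[:, 1]).max(initial=0))
    h, w = mask.shape
    padded = np.pad(mask, ((pr, pr), (pc, pc)), constant_values=False)
    acc = np.ones((h, w), dtype=bool) if require_all else np.zeros((h, w), dtype=bool)
    for dr, dc in offs:
        view = padded[pr + dr : pr + dr + h, pc + dc : pc + dc + w]
        if require_all:
            acc &= view
        else:
            acc |= view
    return acc


def erode(mask: BinaryMask, se: StructuringElement) -> BinaryMask:
    """Erosion: keep pixels whose translated SE fits entirely inside the mask."""
    if se._is_centered_square():
        out = ndimage.minimum_filter(
            mask.pixels, size=se.window.shape[0], mode="constant", cval=False
        )
    else:
        out = _shift_reduce(mask.pixels, se, require_all=True)
    return BinaryMask(out, mask.spacing)


def dilate(mask: BinaryMask, se: StructuringElement) -> BinaryMask:
    """Dilation: mark pixels whose translated SE touches the mask."""
    if se._is_centered_square():
        out = ndimage.maximum_filter(
            mask.pixels, size=se.window.shape[0], mode="constant", cval=False
        )
    else:
        out = _shift_reduce(mask.pixels, se, require_all=False)
    return BinaryMask(out, mask.spacing)


def closing(mask: BinaryMask, se: StructuringElement) -> BinaryMask:
    """Dilation followed by erosion; fills small holes and gulfs."""
    return erode(dilate(mask, se), se)


def opening(mask: BinaryMask, se: StructuringElement) -> BinaryMask:
    """Erosion followed by dilation; removes small islands and spurs."""
    return dilate(erode(mask, se), se)


def mask_xor(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Pixelwise exclusive-or: 1 where the masks differ, 0 where they agree."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return BinaryMask(np.logical_xor(a.pixels, b.pixels), a.spacing)


#: 4-connectivity structure used for the background flood in fill_holes.
_CROSS = ndimage.generate_binary_structure(2, 1)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Set background components not 4-connected to the border to foreground."""
    return BinaryMask(ndimage.binary_fill_holes(mask.pixels, structure=_CROSS), mask.spacing)
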