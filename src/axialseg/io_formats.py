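"""Raster I/O for 2-D axial MR slices and binary masks.

The internal data model is deliberately small: a grayscale slice is a
row-major ``float64`` array with intensities in ``[0, 1]`` plus an in-plane
pixel spacing in millimetres, and a mask is a boolean array on the same
grid.  Origin is the top-left pixel; indexing is 0-based ``(row, col)``.

Supported file formats: 8/16-bit PNG and TIFF, NIfTI-1 (``.nii`` /
``.nii.gz``, with a slice selected from a volume), and single-file DICOM.
Integer rasters are min–max normalised to ``[0, 1]`` on read; floating-point
data already inside ``[0, 1]`` (e.g. a pre-scaled NIfTI) pass through
unchanged.  A constant image normalises to all zeros rather than raising, so
degenerate inputs surface downstream as explicit "no foreground" errors.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "DEFAULT_SPACING",
    "FormatError",
    "GrayImage",
    "BinaryMask",
    "read_image",
    "read_mask",
    "write_image",
    "write_mask",
]

#: Fallback in-plane pixel size (row_mm, col_mm) when a header carries none.
DEFAULT_SPACING: Tuple[float, float] = (0.5, 0.5)

MIN_SIDE = 16


class FormatError(ValueError):
    """Raised when a file cannot be parsed as a supported image format."""


@dataclasses.dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale slice with intensities in [0, 1].

    Parameters
    ----------
    pixels:
        2-D float array, values in ``[0, 1]``.
    spacing:
        Physical pixel size ``(row_mm, col_mm)`` in millimetres.
    """

    pixels: np.ndarray
    spacing: Tuple[float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got shape {arr.shape}")
        if min(arr.shape) < MIN_SIDE:
            raise ValueError(f"image sides must be >= {MIN_SIDE}, got {arr.shape}")
        if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
            raise ValueError("pixel values must lie in [0, 1]")
        arr = np.clip(arr, 0.0, 1.0)
        sp = (float(self.spacing[0]), float(self.spacing[1]))
        if sp[0] <= 0 or sp[1] <= 0:
            raise ValueError(f"spacing components must be > 0, got {sp}")
        object.__setattr__(self, "pixels", arr)
        object.__setattr__(self, "spacing", sp)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclasses.dataclass(frozen=True)
class BinaryMask:
    """A 2-D boolean raster aligned to a :class:`GrayImage` grid."""

    pixels: np.ndarray
    spacing: Tuple[float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D mask, got shape {arr.shape}")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask values must be exactly 0 or 1")
            arr = arr.astype(bool)
        sp = (float(self.spacing[0]), float(self.spacing[1]))
        if sp[0] <= 0 or sp[1] <= 0:
            raise ValueError(f"spacing components must be > 0, got {sp}")
        object.__setattr__(self, "pixels", arr)
        object.__setattr__(self, "spacing", sp)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        """Number of foreground pixels."""
        return int(np.count_nonzero(self.pixels))


def _to_unit(arr: np.ndarray) -> np.ndarray:
    """Normalise raw raster data to [0, 1] (see module docstring)."""
    raw = np.asarray(arr)
    out = raw.astype(np.float64)
    if np.issubdtype(raw.dtype, np.floating):
        finite = out[np.isfinite(out)]
        if finite.size and finite.min() >= 0.0 and finite.max() <= 1.0:
            return out
    lo = float(out.min())
    hi = float(out.max())
    if hi == lo:
        return np.zeros_like(out)
    return (out - lo) / (hi - lo)


def _grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) raster to luminance; pass 2-D data through."""
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64)
        return arr @ np.array([0.299, 0.587, 0.114])
    if arr.ndim != 2:
        raise FormatError(f"cannot interpret array of shape {arr.shape} as a slice")
    return arr


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def _read_raw(path: Path, slice_index: Optional[int]) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Read any supported format; return raw array + spacing (header or default)."""
    if not path.exists():
        raise FileNotFoundError(path)
    sfx = _suffix(path)
    if sfx in (".nii", ".nii.gz"):
        import nibabel as nib

        try:
            img = nib.load(str(path))
        except Exception as exc:  # nibabel raises several unrelated types
            raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        data = np.squeeze(data)
        if data.ndim == 3:
            if slice_index is None:
                raise ValueError(f"{path} holds {data.shape[2]} slices; slice_index is required")
            if not 0 <= slice_index < data.shape[2]:
                raise IndexError(f"slice_index {slice_index} out of range for {data.shape[2]} slices")
            data = data[:, :, slice_index]
        elif data.ndim != 2:
            raise FormatError(f"unsupported NIfTI dimensionality {data.ndim} in {path}")
        zooms = img.header.get_zooms()[:2]
        spacing = (float(zooms[0]), float(zooms[1])) if all(z > 0 for z in zooms) else DEFAULT_SPACING
        return data, spacing
    if sfx in (".dcm", ".dicom", ".ima", ""):
        import pydicom

        try:
            ds = pydicom.dcmread(str(path))
            data = ds.pixel_array
        except Exception as exc:
            raise FormatError(f"cannot read DICOM file {path}: {exc}") from exc
        spacing = DEFAULT_SPACING
        ps = getattr(ds, "PixelSpacing", None)
        if ps is not None and len(ps) == 2:
            spacing = (float(ps[0]), float(ps[1]))
        return _grayscale(np.asarray(data)), spacing
    if sfx in (".png", ".tif", ".tiff"):
        import imageio.v3 as iio

        try:
            data = iio.imread(path)
        except Exception as exc:
            raise FormatError(f"cannot read raster file {path}: {exc}") from exc
        return _grayscale(np.asarray(data)), DEFAULT_SPACING
    raise FormatError(f"unsupported file extension {sfx!r} for {path}")


def read_image(path, slice_index: Optional[int] = None) -> GrayImage:
    """Read a grayscale slice and normalise it to the internal model.

    Parameters
    ----------
    path:
        PNG/TIFF/NIfTI/DICOM file.
    slice_index:
        Required for multi-slice NIfTI volumes; index along the third axis.
    """
    data, spacing = _read_raw(Path(path), slice_index)
    return GrayImage(_to_unit(data), spacing)


def read_mask(path) -> BinaryMask:
    """Read a binary mask; any nonzero pixel becomes foreground."""
    data, spacing = _read_raw(Path(path), None)
    return BinaryMask(np.asarray(data) != 0, spacing)


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as 8-bit {0,255} PNG/TIFF or as uint8 NIfTI.

    ``read_mask(write_mask(m)) == m`` pixel-for-pixel.
    """
    path = Path(path)
    sfx = _suffix(path)
    if sfx in (".nii", ".nii.gz"):
        import nibabel as nib

        affine = np.diag([mask.spacing[0], mask.spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(mask.pixels.astype(np.uint8), affine), str(path))
        return
    if sfx in (".png", ".tif", ".tiff"):
        import imageio.v3 as iio

        iio.imwrite(path, (mask.pixels.astype(np.uint8) * 255))
        return
    raise FormatError(f"unsupported mask output extension {sfx!r}")


def write_image(image: GrayImage, path) -> None:
    """Write a grayscale slice as 8-bit PNG/TIFF or float32 NIfTI."""
    path = Path(path)
    sfx = _suffix(path)
    if sfx in (".nii", ".nii.gz"):
        import nibabel as nib

        affine = np.diag([image.spacing[0], image.spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(image.pixels.astype(np.float32), affine), str(path))
        return
    if sfx in (".png", ".tif", ".tiff"):
        import imageio.v3 as iio

        iio.imwrite(path, np.round(image.pixels * 255).astype(np.uint8))
        return
    raise FormatError(f"unsupported image output extension {sfx!r}")
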