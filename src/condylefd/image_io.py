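"""Grayscale radiograph I/O and region-of-interest extraction.

All images are plain numpy arrays: 8-bit grayscale images are 2-D
``uint8`` arrays, binary masks are 2-D ``bool`` arrays.  Coordinates are
0-based, (row, column) indexed; windows are half-open, so an ROI at
``(x, y)`` with width ``w`` and height ``h`` covers rows ``[y, y+h)`` and
columns ``[x, x+w)`` — the standard raster convention.

Panoramic radiographs arrive as PNG or TIFF (DICOM is supported when
pydicom is installed).  Multi-channel inputs are collapsed by channel
mean; bit depths above 8 are linearly rescaled to [0, 255].
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "ROISpec",
    "ImageInputError",
    "ROIBoundsError",
    "load_grayscale",
    "extract_roi",
    "save_image",
    "as_gray_u8",
]


class ImageInputError(ValueError):
    """Raised when a file cannot be read as a grayscale raster image."""


class ROIBoundsError(ValueError):
    """Raised when an ROI window does not lie fully inside its image."""


@dataclass(frozen=True)
class ROISpec:
    """A fixed-size window anchored at a 0-based top-left corner.

    ``x`` is the column and ``y`` the row of the top-left pixel; the
    default 100x100 window matches the condylar ROI size used for
    trabecular analysis on panoramic radiographs.
    """

    x: int
    y: int
    width: int = 100
    height: int = 100

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"ROI corner must be non-negative, got ({self.x}, {self.y})")
        if self.width < 8 or self.height < 8:
            raise ValueError(
                f"ROI must be at least 8x8 pixels, got {self.width}x{self.height}"
            )


def as_gray_u8(arr: np.ndarray) -> np.ndarray:
    """Validate and return a 2-D uint8 view/copy of ``arr``.

    Accepts integer arrays already within [0, 255]; anything else is an
    error — rescaling happens only at load time where the source bit
    depth is known.
    """
    a = np.asarray(arr)
    if a.ndim != 2 or a.size == 0:
        raise ImageInputError(f"expected a non-empty 2-D image, got shape {a.shape}")
    if a.dtype == np.uint8:
        return a
    if not np.issubdtype(a.dtype, np.integer):
        raise ImageInputError(f"expected integer intensities, got dtype {a.dtype}")
    if a.min() < 0 or a.max() > 255:
        raise ImageInputError("integer intensities outside [0, 255]")
    return a.astype(np.uint8)


def _rescale_to_u8(arr: np.ndarray) -> np.ndarray:
    """Linearly map an array to uint8 based on its dtype's full range."""
    if arr.dtype == np.uint8:
        return arr
    if np.issubdtype(arr.dtype, np.integer):
        # Map the dtype's representable range onto [0, 255].
        info = np.iinfo(arr.dtype)
        lo, hi = (0, info.max) if info.min == 0 else (info.min, info.max)
        scaled = (arr.astype(np.float64) - lo) * (255.0 / (hi - lo))
    elif np.issubdtype(arr.dtype, np.floating):
        scaled = np.clip(arr.astype(np.float64), 0.0, 1.0) * 255.0
    else:
        raise ImageInputError(f"unsupported pixel dtype {arr.dtype}")
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def _load_dicom(path: str) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - env-dependent
        raise ImageInputError(
            f"cannot read DICOM file {path!r}: pydicom is not installed"
        ) from exc
    ds = pydicom.dcmread(path)
    arr = np.asarray(ds.pixel_array)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.clip(np.rint((arr - lo) * (255.0 / (hi - lo))), 0, 255).astype(np.uint8)


def load_grayscale(path: str | os.PathLike) -> np.ndarray:
    """Load a raster image as a 2-D uint8 grayscale array.

    Multi-channel images are collapsed by channel mean before rescaling;
    bit depths above 8 are linearly mapped onto [0, 255].
    """
    path = os.fspath(path)
    if path.lower().endswith((".dcm", ".dicom")):
        return _load_dicom(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise ImageInputError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.size == 0:
        raise ImageInputError(f"zero-area image: {path!r}")
    if arr.ndim == 3:
        src_dtype = arr.dtype
        mean = arr.astype(np.float64).mean(axis=-1)
        if src_dtype == np.uint8:
            arr = np.clip(np.rint(mean), 0, 255).astype(np.uint8)
        else:
            arr = mean.astype(src_dtype)
    if arr.ndim != 2:
        raise ImageInputError(f"cannot interpret {path!r} as a 2-D image (shape {arr.shape})")
    if arr.dtype != np.uint8:
        arr = _rescale_to_u8(arr)
    return arr


def extract_roi(img: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Copy the half-open window [y, y+h) x [x, x+w) out of ``img``.

    The returned array owns its data, so editing the ROI never mutates
    the source radiograph.
    """
    h, w = img.shape[:2]
    over_x = roi.x + roi.width - w
    over_y = roi.y + roi.height - h
    if over_x > 0 or over_y > 0:
        parts = []
        if over_x > 0:
            parts.append(f"x+width={roi.x + roi.width} exceeds image width {w} by {over_x}")
        if over_y > 0:
            parts.append(f"y+height={roi.y + roi.height} exceeds image height {h} by {over_y}")
        raise ROIBoundsError("ROI outside image: " + "; ".join(parts))
    return np.array(img[roi.y : roi.y + roi.height, roi.x : roi.x + roi.width], copy=True)


def save_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write a grayscale or binary image losslessly (PNG/TIFF).

    Binary masks are written as {0, 255} so the round trip through
    :func:`load_grayscale` followed by thresholding is exact.
    """
    path = os.fspath(path)
    arr = np.asarray(img)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    arr = as_gray_u8(arr)
    try:
        Image.fromarray(arr, mode="L").save(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot write image to {path!r}: {exc}") from exc
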