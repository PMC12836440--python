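"""The ten-step preprocessing chain that turns a grayscale ROI into a
skeletonized binary trabecular pattern.

The chain mirrors the classical automated protocol for trabecular bone
texture on dental radiographs:

1. extract the ROI; 2. duplicate it; 3. Gaussian-blur the duplicate to
estimate the large-scale density background; 4. subtract the blurred
image from the duplicate (leaving fine trabecular texture); 5. add 128
gray levels to recenter; 6. binarize at a fixed threshold; 7. erode and
8. dilate with a 3x3 square element (a morphological opening that
removes binarization noise); 9. invert; 10. skeletonize to 1-pixel-wide
curves.

All arithmetic is 8-bit saturating (clamped to [0, 255]); blur borders
use edge replication; morphology treats out-of-image neighbours as
background.  The whole trace is a pure function of (pixels, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _sk_skeletonize

from .image_io import ROISpec, as_gray_u8, extract_roi

__all__ = [
    "PipelineConfig",
    "PipelineTrace",
    "STEP_NAMES",
    "gaussian_blur",
    "subtract",
    "add_offset",
    "binarize",
    "erode",
    "dilate",
    "invert",
    "skeletonize",
    "preprocess",
]

#: Step labels in execution order; the first five are grayscale, the
#: last five binary.
STEP_NAMES = (
    "roi",
    "duplicate",
    "blurred",
    "subtracted",
    "offset_added",
    "binary",
    "eroded",
    "dilated",
    "inverted",
    "skeleton",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the preprocessing chain.

    gaussian_sigma : blur scale in pixels (default 35, the established
        background-subtraction scale for 100x100 dental-radiograph ROIs).
    offset : gray levels added after subtraction; fixed at 128 so the
        texture is recentred on mid-gray.
    binarize_threshold : foreground where intensity is strictly greater
        (default 128, i.e. brighter than the recentred background).
    morphology_radius / morphology_iterations : square structuring
        element of side 2*radius+1 and repetition count for the
        erosion/dilation pair.
    """

    gaussian_sigma: float = 35.0
    offset: int = 128
    binarize_threshold: int = 128
    morphology_radius: int = 1
    morphology_iterations: int = 1

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError(f"gaussian_sigma must be > 0, got {self.gaussian_sigma}")
        if self.offset != 128:
            raise ValueError(f"offset is fixed at 128 gray levels, got {self.offset}")
        if not 0 < self.binarize_threshold < 255:
            raise ValueError(
                f"binarize_threshold must be in (0, 255), got {self.binarize_threshold}"
            )
        if self.morphology_radius < 1:
            raise ValueError(f"morphology_radius must be >= 1, got {self.morphology_radius}")
        if self.morphology_iterations < 1:
            raise ValueError(
                f"morphology_iterations must be >= 1, got {self.morphology_iterations}"
            )


@dataclass(frozen=True)
class PipelineTrace:
    """All ten intermediate images of one preprocessing run."""

    steps: dict[str, np.ndarray]
    config: PipelineConfig
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        if tuple(self.steps) != STEP_NAMES:
            raise ValueError(f"trace must contain exactly the steps {STEP_NAMES}")

    @property
    def skeleton(self) -> np.ndarray:
        return self.steps["skeleton"]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.steps[name]


def gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Isotropic Gaussian blur with edge replication, rounded to uint8."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    img = as_gray_u8(img)
    out = ndi.gaussian_filter(img.astype(np.float64), sigma=sigma, mode="nearest")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixelwise a - b with saturation at 0."""
    a = as_gray_u8(a)
    b = as_gray_u8(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.maximum(a.astype(np.int16) - b.astype(np.int16), 0).astype(np.uint8)


def add_offset(img: np.ndarray, offset: int = 128) -> np.ndarray:
    """Pixelwise img + offset with saturation at 255."""
    if not 0 <= offset <= 255:
        raise ValueError(f"offset must be in [0, 255], got {offset}")
    img = as_gray_u8(img)
    return np.minimum(img.astype(np.int16) + offset, 255).astype(np.uint8)


def binarize(img: np.ndarray, threshold: int = 128) -> np.ndarray:
    """Foreground where intensity is strictly greater than ``threshold``."""
    if not 0 < threshold < 255:
        raise ValueError(f"threshold must be in (0, 255), got {threshold}")
    return as_gray_u8(img) > threshold


def _square_element(radius: int) -> np.ndarray:
    return np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)


def erode(
    mask: np.ndarray,
    radius: int = 1,
    iterations: int = 1,
    border: str = "background",
) -> np.ndarray:
    """Binary erosion with a square structuring element.

    ``border`` controls how out-of-image neighbours are treated:
    "background" (default, border pixels are eroded away) or
    "foreground" (the mirrored convention under which erosion and
    dilation are exact duals).
    """
    mask = np.asarray(mask, dtype=bool)
    border_value = {"background": 0, "foreground": 1}[border]
    return ndi.binary_erosion(
        mask,
        structure=_square_element(radius),
        iterations=iterations,
        border_value=border_value,
    )


def dilate(mask: np.ndarray, radius: int = 1, iterations: int = 1) -> np.ndarray:
    """Binary dilation, same element as :func:`erode`, background border."""
    mask = np.asarray(mask, dtype=bool)
    return ndi.binary_dilation(
        mask,
        structure=_square_element(radius),
        iterations=iterations,
        border_value=0,
    )


def invert(mask: np.ndarray) -> np.ndarray:
    """Swap foreground and background (an involution)."""
    return ~np.asarray(mask, dtype=bool)


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin foreground to 1-pixel-wide curves (Zhang-Suen-type).

    The skeleton is a subset of the input foreground and preserves the
    number of 8-connected foreground components.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    return _sk_skeletonize(mask).astype(bool)


def preprocess(
    img: np.ndarray,
    roi: ROISpec,
    config: PipelineConfig | None = None,
) -> PipelineTrace:
    """Run the full ten-step chain on one ROI and return every intermediate.

    If no foreground survives the morphological opening (e.g. a flat,
    textureless ROI), the trace is flagged degenerate and the inverted
    and skeleton steps are left empty: there is no trabecular pattern to
    invert, and thinning the complement of nothing would manufacture a
    spurious structure out of the image border.
    """
    config = config or PipelineConfig()
    roi_img = extract_roi(as_gray_u8(img), roi)
    duplicate = roi_img.copy()
    blurred = gaussian_blur(duplicate, config.gaussian_sigma)
    subtracted = subtract(duplicate, blurred)
    offset_added = add_offset(subtracted, config.offset)
    binary = binarize(offset_added, config.binarize_threshold)
    eroded = erode(binary, config.morphology_radius, config.morphology_iterations)
    dilated = dilate(eroded, config.morphology_radius, config.morphology_iterations)
    degenerate = not dilated.any()
    if degenerate:
        inverted = np.zeros_like(dilated)
        skeleton = np.zeros_like(dilated)
    else:
        inverted = invert(dilated)
        skeleton = skeletonize(inverted)
    steps = dict(
        zip(
            STEP_NAMES,
            (
                roi_img,
                duplicate,
                blurred,
                subtracted,
                offset_added,
                binary,
                eroded,
                dilated,
                inverted,
                skeleton,
            ),
        )
    )
    return PipelineTrace(steps=steps, config=config, degenerate=degenerate)
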