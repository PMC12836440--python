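"""Box-counting fractal dimension of binary images.

The estimator covers the image with a grid of square cells of edge
length eps (anchored at the top-left corner; edge cells may be partial),
counts the cells N(eps) containing at least one foreground pixel, and
fits log N(eps) against log eps by ordinary least squares.  The fractal
dimension is the negated slope, so a 1-pixel curve has FD ~ 1 and a
filled region FD ~ 2.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .image_io import ROISpec, as_gray_u8
from .pipeline import PipelineConfig, PipelineTrace, preprocess

__all__ = [
    "DEFAULT_BOX_SIZES",
    "BoxCountResult",
    "FDRecord",
    "EmptyForegroundError",
    "DegenerateROIError",
    "FDRangeError",
    "count_boxes",
    "fractal_dimension",
    "fd_from_image",
]

#: Default box-edge schedule in pixels; sizes above min(W, H) are
#: dropped at fit time.  The schedule is echoed in every output record
#: because FD values are only comparable under the same schedule.
DEFAULT_BOX_SIZES = (2, 3, 4, 6, 8, 12, 16, 32, 64)


class EmptyForegroundError(ValueError):
    """Raised when an image has no foreground to measure."""


class DegenerateROIError(ValueError):
    """Raised when a ROI yields no trabecular pattern (empty skeleton)."""


class FDRangeError(RuntimeError):
    """Raised when a fitted dimension falls outside the valid (0, 2] range."""


@dataclass(frozen=True)
class BoxCountResult:
    """Grid counts and the log-log regression they support."""

    box_sizes: tuple[int, ...]
    counts: tuple[int, ...]
    slope: float
    intercept: float
    r_squared: float
    fd: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FDRecord:
    """One structured per-condyle measurement (the unit of batch output)."""

    subject_id: str
    side: str
    fd: float
    r_squared: float
    trace: PipelineTrace
    result: BoxCountResult

    def to_dict(self) -> dict:
        cfg = self.trace.config
        return {
            "subject": self.subject_id,
            "side": self.side,
            "fd": self.fd,
            "slope": self.result.slope,
            "intercept": self.result.intercept,
            "r_squared": self.r_squared,
            "box_sizes": list(self.result.box_sizes),
            "counts": list(self.result.counts),
            "config": {
                "gaussian_sigma": cfg.gaussian_sigma,
                "offset": cfg.offset,
                "binarize_threshold": cfg.binarize_threshold,
                "morphology_radius": cfg.morphology_radius,
                "morphology_iterations": cfg.morphology_iterations,
            },
        }


def count_boxes(mask: np.ndarray, size: int) -> int:
    """Number of grid cells of edge ``size`` holding >= 1 foreground pixel.

    The grid is anchored at the top-left corner; cells on the right and
    bottom edges may be partial.  An empty image counts 0.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if not 1 <= size <= min(h, w):
        raise ValueError(f"box size must be in [1, {min(h, w)}], got {size}")
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        return 0
    ncols = -(-w // size)  # ceil(w / size)
    cells = (rr // size) * ncols + (cc // size)
    return int(np.unique(cells).size)


def fractal_dimension(
    mask: np.ndarray,
    box_sizes: Sequence[int] | None = None,
) -> BoxCountResult:
    """OLS fit of log N(eps) on log eps; fd is the negated slope.

    Box sizes larger than the shorter image side are dropped; at least
    three usable sizes are required.  The fitted dimension must land in
    (0, 2] for a 2-D binary image — anything else raises a diagnostic
    rather than returning silently.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyForegroundError("no foreground to measure")
    limit = min(mask.shape)
    sizes = sorted({int(s) for s in (box_sizes or DEFAULT_BOX_SIZES) if 1 <= int(s) <= limit})
    if len(sizes) < 3:
        raise ValueError(
            f"need >= 3 usable box sizes <= {limit}, got {sizes!r}"
        )
    counts = [count_boxes(mask, s) for s in sizes]
    x = np.log(np.asarray(sizes, dtype=np.float64))
    y = np.log(np.asarray(counts, dtype=np.float64))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    fd = -float(slope)
    if not 0.0 < fd <= 2.0 + 1e-9:
        raise FDRangeError(
            f"fitted dimension {fd:.4f} outside (0, 2]; counts={counts}, sizes={sizes}"
        )
    return BoxCountResult(
        box_sizes=tuple(sizes),
        counts=tuple(counts),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r_squared),
        fd=fd,
    )


def fd_from_image(
    img: np.ndarray,
    roi: ROISpec,
    config: PipelineConfig | None = None,
    box_sizes: Sequence[int] | None = None,
    subject_id: str = "",
    side: str = "",
) -> FDRecord:
    """Preprocess one ROI and box-count its skeleton (one condyle's FD)."""
    trace = preprocess(as_gray_u8(img), roi, config)
    if trace.degenerate or not trace.skeleton.any():
        raise DegenerateROIError(
            "degenerate ROI: preprocessing produced no trabecular pattern"
        )
    result = fractal_dimension(trace.skeleton, box_sizes)
    return FDRecord(
        subject_id=subject_id,
        side=side,
        fd=result.fd,
        r_squared=result.r_squared,
        trace=trace,
        result=result,
    )
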