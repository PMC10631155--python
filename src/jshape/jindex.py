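"""The J index: shared area over non-shared area against the fitted ellipse.

For a segmented region A and its fitted ellipse rasterized onto the same
grid, E::

    J = |A ∩ E| / |A Δ E|

where the denominator is the symmetric difference — the area in exactly one
of the two regions (note this is NOT the Jaccard index |A∩E|/|A∪E|; the two
are related by J = Jaccard / (1 - Jaccard)).  A perfectly elliptical region
has a large J; deviations from ellipticity push area into the symmetric
difference and J falls.

Overlap is computed by pixel-center membership on the segmentation's own
grid, which matches how the segmentation itself is defined and makes the
pixel-count arithmetic exact: ``|A| + |E| = 2|A∩E| + |AΔE|`` holds as an
integer identity on every input.

A slice whose segmentation coincides exactly with the rasterized ellipse has
a zero denominator; its J is flagged degenerate (the continuous-limit value
is infinite) rather than capped, and such slices are excluded from means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .ellipse_fit import EllipseFit, ellipse_contains, fit_ellipse_to_mask
from .exceptions import EmptyRegionError
from .mask_io import CrossSectionMask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class JIndexResult:
    """J index of one slice, with the pixel-count bookkeeping behind it."""

    intersection_mm2: float
    sym_diff_mm2: float
    j: float  # NaN when degenerate
    mask_area_mm2: float
    ellipse_area_mm2: float
    degenerate: bool
    mask_pixels: int
    intersection_pixels: int
    sym_diff_pixels: int

    def __post_init__(self) -> None:
        if self.degenerate != (self.sym_diff_pixels == 0):
            raise ValueError("degenerate flag inconsistent with sym_diff")


def pixel_center_grid(
    shape: tuple[int, int], pixel_spacing_mm: tuple[float, float]
) -> np.ndarray:
    """(rows*cols, 2) array of pixel-center (x, y) coordinates in mm."""
    sy, sx = pixel_spacing_mm
    rows, cols = shape
    x = (np.arange(cols) + 0.5) * sx
    y = (np.arange(rows) + 0.5) * sy
    xx, yy = np.meshgrid(x, y)
    return np.column_stack([xx.ravel(), yy.ravel()])


def rasterize_ellipse(e: EllipseFit, template: CrossSectionMask) -> CrossSectionMask:
    """Pixel-center rasterization of an ellipse onto a template's grid.

    Foreground = pixels whose centers lie inside the (closed) ellipse.  If
    the ellipse's bounding box extends beyond the grid's physical extent the
    rasterization is clipped and a warning logged.
    """
    shape = template.grid.shape
    pts = pixel_center_grid(shape, template.pixel_spacing_mm)
    inside = ellipse_contains(e, pts).reshape(shape)
    sy, sx = template.pixel_spacing_mm
    cx, cy = e.center
    a = e.semi_major_mm
    if (
        cx - a < 0
        or cy - a < 0
        or cx + a > shape[1] * sx
        or cy + a > shape[0] * sy
    ):
        logger.warning(
            "ellipse (center %.1f, %.1f mm; a=%.1f mm) extends beyond the "
            "%sx%s grid; rasterization clipped",
            cx, cy, a, shape[0], shape[1],
        )
    return CrossSectionMask(
        grid=inside,
        pixel_spacing_mm=template.pixel_spacing_mm,
        slice_index=template.slice_index,
        muscle=template.muscle,
    )


def compute_j_index(mask: CrossSectionMask, e: EllipseFit) -> JIndexResult:
    """J index of a mask against an ellipse rasterized onto the mask's grid."""
    if mask.n_foreground == 0:
        raise EmptyRegionError("cannot compute the J index of an empty mask")
    ellipse_mask = rasterize_ellipse(e, mask)
    inter_px = int(np.logical_and(mask.grid, ellipse_mask.grid).sum())
    sym_px = int(np.logical_xor(mask.grid, ellipse_mask.grid).sum())
    px_area = mask.pixel_area_mm2
    degenerate = sym_px == 0
    return JIndexResult(
        intersection_mm2=inter_px * px_area,
        sym_diff_mm2=sym_px * px_area,
        j=math.nan if degenerate else inter_px / sym_px,
        mask_area_mm2=mask.area_mm2,
        ellipse_area_mm2=ellipse_mask.area_mm2,
        degenerate=degenerate,
        mask_pixels=mask.n_foreground,
        intersection_pixels=inter_px,
        sym_diff_pixels=sym_px,
    )


def j_index_of_mask(
    mask: CrossSectionMask, scaling: str = "moment"
) -> tuple[EllipseFit, JIndexResult]:
    """Fit the moment ellipse to a mask and score the mask against it."""
    fit = fit_ellipse_to_mask(mask, scaling=scaling)
    return fit, compute_j_index(mask, fit)
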