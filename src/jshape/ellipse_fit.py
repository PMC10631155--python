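"""Covariance-based best-fitting ellipse of a segmented cross-section.

The cross-sectional shape of a muscle is summarised by the ellipse derived
from the second moments of its foreground-pixel point cloud: the center is
the centroid, the axes follow the eigenvectors of the 2x2 covariance matrix,
and — because a uniformly filled elliptical lamina with semi-axes ``a, b``
has covariance eigenvalues exactly ``a**2 / 4`` and ``b**2 / 4`` — the
semi-axis lengths are taken as ``2 * sqrt(eigenvalue)``.  This scaling is
parameter-free and reproduces a true ellipse exactly; an alternative
area-matching scaling (both axes rescaled so the ellipse area equals the
region area) is available via ``scaling="area"``.

The covariance uses the population normalisation (divide by N): the lamina
moment identities above hold for that form, and it is what
``skimage.measure.regionprops`` uses for its moment ellipse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateGeometryError,
    EmptyRegionError,
    InsufficientPointsError,
)
from .mask_io import CrossSectionMask

#: Relative eigenvalue gap below which the cloud is treated as circular and
#: the orientation pinned to 0 deg (a circle has no principal axis).
ORIENTATION_TIE_RTOL = 1e-9
#: lambda2/lambda1 below this means a (near-)collinear cloud: no ellipse.
DEGENERACY_RTOL = 1e-6


@dataclass(frozen=True)
class PointCloud:
    """Physical pixel-center coordinates of a mask's foreground, in mm.

    ``points`` has shape (n, 2) with columns (x, y); x runs along image
    columns, y along rows, both measured at pixel centers
    ``(index + 0.5) * spacing``.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must have shape (n, 2), got {pts.shape}")
        if pts.shape[0] < 1:
            raise ValueError("point cloud must contain at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return int(self.points.shape[0])


@dataclass(frozen=True)
class EllipseFit:
    """Moment ellipse of a point cloud.

    Attributes
    ----------
    center : (float, float)
        Centroid (x, y) in mm.
    semi_major_mm, semi_minor_mm : float
        Semi-axis lengths ``a >= b > 0``.
    orientation_deg : float
        Angle of the major axis to the +x axis, in [0, 180).
    aspect_ratio : float
        ``a / b`` (>= 1).
    eigenvalues : (float, float)
        Covariance eigenvalues (lambda1 >= lambda2), mm^2.
    """

    center: tuple[float, float]
    semi_major_mm: float
    semi_minor_mm: float
    orientation_deg: float
    aspect_ratio: float
    eigenvalues: tuple[float, float]

    @property
    def area_mm2(self) -> float:
        """Continuous area pi*a*b of the fitted ellipse."""
        return math.pi * self.semi_major_mm * self.semi_minor_mm


def mask_to_point_cloud(mask: CrossSectionMask) -> PointCloud:
    """One point per foreground pixel, at the pixel's physical center."""
    rows, cols = np.nonzero(mask.grid)
    if rows.size == 0:
        raise EmptyRegionError(
            f"mask for {mask.muscle or '<unnamed>'} slice {mask.slice_index} is empty"
        )
    sy, sx = mask.pixel_spacing_mm
    x = (cols + 0.5) * sx
    y = (rows + 0.5) * sy
    return PointCloud(points=np.column_stack([x, y]))


def point_cloud_covariance(cloud: PointCloud) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and population (divide-by-N) covariance of a point cloud."""
    center = cloud.points.mean(axis=0)
    centered = cloud.points - center
    cov = centered.T @ centered / cloud.n
    return center, cov


def fit_ellipse(cloud: PointCloud) -> EllipseFit:
    """Fit the covariance (moment) ellipse to a point cloud.

    Semi-axes are ``2*sqrt(eigenvalue)``; see :func:`fit_ellipse_to_mask`
    for the optional area-matching rescaling.

    Raises
    ------
    InsufficientPointsError
        Fewer than 3 points.
    DegenerateGeometryError
        lambda2/lambda1 below the degeneracy tolerance (collinear cloud).
    """
    if cloud.n < 3:
        raise InsufficientPointsError(
            f"need >= 3 points to fit an ellipse, got {cloud.n}"
        )
    center, cov = point_cloud_covariance(cloud)
    # eigh returns ascending eigenvalues for the symmetric 2x2 covariance
    eigvals, eigvecs = np.linalg.eigh(cov)
    lam2, lam1 = float(eigvals[0]), float(eigvals[1])
    lam2 = max(lam2, 0.0)
    if lam1 <= 0.0 or lam2 / lam1 < DEGENERACY_RTOL:
        raise DegenerateGeometryError(
            f"point cloud is degenerate (eigenvalues {lam1:.3g}, {lam2:.3g})"
        )
    if (lam1 - lam2) <= ORIENTATION_TIE_RTOL * lam1:
        orientation = 0.0
    else:
        vx, vy = eigvecs[:, 1]
        orientation = math.degrees(math.atan2(vy, vx)) % 180.0
    a = 2.0 * math.sqrt(lam1)
    b = 2.0 * math.sqrt(lam2)
    return EllipseFit(
        center=(float(center[0]), float(center[1])),
        semi_major_mm=a,
        semi_minor_mm=b,
        orientation_deg=orientation,
        aspect_ratio=a / b,
        eigenvalues=(lam1, lam2),
    )


def fit_ellipse_to_mask(
    mask: CrossSectionMask, scaling: str = "moment"
) -> EllipseFit:
    """Moment ellipse of a mask's foreground pixels.

    With ``scaling="area"`` the moment ellipse's axes are both multiplied by
    the factor that makes the continuous ellipse area equal the mask area
    (aspect ratio and orientation unchanged).
    """
    fit = fit_ellipse(mask_to_point_cloud(mask))
    if scaling == "moment":
        return fit
    if scaling != "area":
        raise ValueError(f"unknown scaling {scaling!r}")
    factor = math.sqrt(mask.area_mm2 / fit.area_mm2)
    return EllipseFit(
        center=fit.center,
        semi_major_mm=fit.semi_major_mm * factor,
        semi_minor_mm=fit.semi_minor_mm * factor,
        orientation_deg=fit.orientation_deg,
        aspect_ratio=fit.aspect_ratio,
        eigenvalues=fit.eigenvalues,
    )


def ellipse_contains(
    e: EllipseFit, points: np.ndarray | tuple[float, float]
) -> np.ndarray | bool:
    """Closed-region membership test, vectorised over an (n, 2) array.

    A point is inside iff, after translating to the ellipse center and
    rotating by -orientation, ``(x/a)**2 + (y/b)**2 <= 1``.  Boundary points
    count as inside.
    """
    pts = np.asarray(points, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    theta = math.radians(e.orientation_deg)
    c, s = math.cos(theta), math.sin(theta)
    dx = pts[:, 0] - e.center[0]
    dy = pts[:, 1] - e.center[1]
    u = c * dx + s * dy
    v = -s * dx + c * dy
    q = (u / e.semi_major_mm) ** 2 + (v / e.semi_minor_mm) ** 2
    inside = q <= 1.0 + 1e-12
    return bool(inside[0]) if scalar else inside
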