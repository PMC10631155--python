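"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorised code paths:
covariance by an explicit Python loop over enumerated pixel centers, and
region overlap by a double loop testing each pixel individually.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from jshape import CrossSectionMask, ellipse_contains


def brute_force_covariance(mask: CrossSectionMask):
    """Centroid and population covariance via an explicit per-pixel loop."""
    sy, sx = mask.pixel_spacing_mm
    pts = []
    for r in range(mask.grid.shape[0]):
        for c in range(mask.grid.shape[1]):
            if mask.grid[r, c]:
                pts.append(((c + 0.5) * sx, (r + 0.5) * sy))
    n = len(pts)
    cx = sum(p[0] for p in pts) / n
    cy = sum(p[1] for p in pts) / n
    sxx = sum((p[0] - cx) ** 2 for p in pts) / n
    syy = sum((p[1] - cy) ** 2 for p in pts) / n
    sxy = sum((p[0] - cx) * (p[1] - cy) for p in pts) / n
    return (cx, cy), np.array([[sxx, sxy], [sxy, syy]])


def brute_force_overlap(mask: CrossSectionMask, ellipse):
    """Intersection / symmetric-difference pixel counts by a double loop."""
    sy, sx = mask.pixel_spacing_mm
    inter = sym = 0
    for r in range(mask.grid.shape[0]):
        for c in range(mask.grid.shape[1]):
            in_mask = bool(mask.grid[r, c])
            in_ellipse = bool(
                ellipse_contains(ellipse, ((c + 0.5) * sx, (r + 0.5) * sy))
            )
            if in_mask and in_ellipse:
                inter += 1
            elif in_mask != in_ellipse:
                sym += 1
    return inter, sym


def disc_mask(radius_px: float, n: int = 64, spacing=(1.0, 1.0)) -> CrossSectionMask:
    yy, xx = np.mgrid[0:n, 0:n]
    cx = cy = n / 2
    grid = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= radius_px**2
    return CrossSectionMask(grid, spacing)


def rectangle_mask(
    w: int = 60, h: int = 30, pad: int = 20, angle_deg: float = 0.0,
    spacing=(1.0, 1.0),
) -> CrossSectionMask:
    """Filled w x h rectangle, optionally rotated about its center before
    pixel-center rasterization."""
    n = int(math.ceil(math.hypot(w, h))) + 2 * pad
    yy, xx = np.mgrid[0:n, 0:n]
    x = xx + 0.5 - n / 2
    y = yy + 0.5 - n / 2
    t = math.radians(angle_deg)
    u = math.cos(t) * x + math.sin(t) * y
    v = -math.sin(t) * x + math.cos(t) * y
    grid = (np.abs(u) <= w / 2) & (np.abs(v) <= h / 2)
    return CrossSectionMask(grid, spacing)


def random_blob_mask(seed: int, n: int = 48, spacing=(1.0, 1.0)) -> CrossSectionMask:
    """Connected random blob: union of a few overlapping discs."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:n, 0:n]
    grid = np.zeros((n, n), bool)
    cx, cy = n / 2, n / 2
    for _ in range(rng.integers(2, 5)):
        r = rng.uniform(5, 10)
        grid |= (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= r**2
        cx += rng.uniform(-6, 6)
        cy += rng.uniform(-6, 6)
    return CrossSectionMask(grid, spacing)


@pytest.fixture(scope="session")
def disc20():
    return disc_mask(20.0)


@pytest.fixture(scope="session")
def rect60x30():
    return rectangle_mask(60, 30)


@pytest.fixture(scope="session")
def blob_masks():
    return [random_blob_mask(seed) for seed in range(5)]


@pytest.fixture(scope="session")
def small_phantom_study():
    """A reduced seven-muscle, three-position phantom shared across tests."""
    from jshape import default_study_spec, generate_study

    spec = default_study_spec(seed=7, n_slices=8, boundary_noise_sd_mm=0.3)
    return generate_study(spec)
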