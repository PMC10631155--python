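"""Covariance ellipse fitting: oracles, analytic moments, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jshape import (
    CrossSectionMask,
    EllipseFit,
    PointCloud,
    ellipse_contains,
    fit_ellipse,
    fit_ellipse_to_mask,
    mask_to_point_cloud,
)
from jshape.exceptions import (
    DegenerateGeometryError,
    EmptyRegionError,
    InsufficientPointsError,
)

from .conftest import brute_force_covariance, disc_mask, random_blob_mask, rectangle_mask


class TestMaskToPointCloud:
    def test_single_pixel_center_convention(self):
        grid = np.zeros((3, 3), bool)
        grid[0, 0] = True
        cloud = mask_to_point_cloud(CrossSectionMask(grid, (1.0, 1.0)))
        assert cloud.n == 1
        np.testing.assert_allclose(cloud.points, [[0.5, 0.5]])

    def test_block_centroid_and_anisotropic_spacing(self):
        grid = np.zeros((4, 4), bool)
        grid[0:2, 0:2] = True
        cloud = mask_to_point_cloud(CrossSectionMask(grid, (1.0, 1.0)))
        assert cloud.n == 4
        np.testing.assert_allclose(cloud.points.mean(axis=0), [1.0, 1.0])
        # anisotropic spacing stretches y (rows) only
        cloud2 = mask_to_point_cloud(CrossSectionMask(grid, (3.0, 0.65)))
        np.testing.assert_allclose(cloud2.points.mean(axis=0), [0.65, 3.0])

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRegionError):
            mask_to_point_cloud(CrossSectionMask(np.zeros((3, 3), bool), (1, 1)))


class TestFitOracleEquivalence:
    """fit_ellipse must agree exactly with the enumerated-pixel oracle."""

    @pytest.mark.parametrize("seed", range(5))
    def test_covariance_matches_brute_force_on_blobs(self, seed):
        mask = random_blob_mask(seed)
        center, cov = brute_force_covariance(mask)
        fit = fit_ellipse_to_mask(mask)
        eigvals = np.linalg.eigvalsh(cov)
        np.testing.assert_allclose(fit.center, center, rtol=0, atol=1e-12)
        np.testing.assert_allclose(
            sorted(fit.eigenvalues), eigvals, rtol=1e-12, atol=0
        )

    def test_orientation_matches_brute_force_eigenvector(self):
        mask = rectangle_mask(40, 18, angle_deg=25.0)
        _, cov = brute_force_covariance(mask)
        w, v = np.linalg.eigh(cov)
        expected = math.degrees(math.atan2(v[1, 1], v[0, 1])) % 180.0
        fit = fit_ellipse_to_mask(mask)
        assert fit.orientation_deg == pytest.approx(expected, abs=1e-9)

    def test_matches_skimage_moment_ellipse(self):
        """Independent cross-check: regionprops' moment ellipse uses the same
        construction (axis length = 4 sqrt(lambda)) on an isotropic grid."""
        skimage_measure = pytest.importorskip("skimage.measure")
        mask = random_blob_mask(3)
        props = skimage_measure.regionprops(mask.grid.astype(int))[0]
        fit = fit_ellipse_to_mask(mask)
        assert fit.semi_major_mm == pytest.approx(props.axis_major_length / 2, rel=1e-9)
        assert fit.semi_minor_mm == pytest.approx(props.axis_minor_length / 2, rel=1e-9)


class TestAnalyticMoments:
    """Recovery of closed-form lamina moments: disc lambda = r^2/4,
    rectangle lambda = w^2/12 -> a = w/sqrt(3)."""

    def test_disc_radius_recovery(self, disc20):
        fit = fit_ellipse_to_mask(disc20)
        assert fit.semi_major_mm == pytest.approx(20.0, rel=0.02)
        assert fit.semi_minor_mm == pytest.approx(20.0, rel=0.02)

    def test_rectangle_axes_and_aspect(self, rect60x30):
        fit = fit_ellipse_to_mask(rect60x30)
        assert fit.aspect_ratio == pytest.approx(2.0, rel=0.02)
        assert fit.semi_major_mm == pytest.approx(60 / math.sqrt(3), rel=0.02)
        assert fit.orientation_deg == pytest.approx(0.0, abs=2.0)

    @pytest.mark.parametrize("angle", [30.0, 75.0, 120.0])
    def test_rotated_rectangle_orientation(self, angle):
        fit = fit_ellipse_to_mask(rectangle_mask(60, 30, angle_deg=angle))
        assert fit.orientation_deg == pytest.approx(angle % 180.0, abs=2.0)
        assert fit.aspect_ratio == pytest.approx(2.0, rel=0.02)

    @pytest.mark.parametrize("a,b,theta", [(20, 15, 0.0), (25, 16, 40.0), (18, 15, 155.0)])
    def test_generated_ellipse_parameter_recovery(self, a, b, theta):
        from jshape import generate_ellipse_mask

        mask = generate_ellipse_mask(a, b, theta, (40.0, 40.0), (80, 80), (1.0, 1.0))
        fit = fit_ellipse_to_mask(mask)
        assert fit.semi_major_mm == pytest.approx(a, rel=0.02)
        assert fit.semi_minor_mm == pytest.approx(b, rel=0.02)
        assert fit.orientation_deg == pytest.approx(theta, abs=2.0)


class TestRigidMotionEquivariance:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
        rot=st.floats(0, 179),
    )
    def test_translation_and_rotation(self, dx, dy, rot):
        base = mask_to_point_cloud(rectangle_mask(40, 18, pad=5)).points
        fit0 = fit_ellipse(PointCloud(base))
        t = math.radians(rot)
        R = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
        moved = base @ R.T + [dx, dy]
        fit1 = fit_ellipse(PointCloud(moved))
        assert fit1.semi_major_mm == pytest.approx(fit0.semi_major_mm, rel=1e-9)
        assert fit1.semi_minor_mm == pytest.approx(fit0.semi_minor_mm, rel=1e-9)
        assert fit1.aspect_ratio == pytest.approx(fit0.aspect_ratio, rel=1e-9)
        expected_center = R @ np.asarray(fit0.center) + [dx, dy]
        np.testing.assert_allclose(fit1.center, expected_center, atol=1e-8)
        expected_orient = (fit0.orientation_deg + rot) % 180.0
        diff = abs(fit1.orientation_deg - expected_orient) % 180.0
        assert min(diff, 180.0 - diff) < 1e-6


class TestDegenerateInputs:
    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            fit_ellipse(PointCloud(np.array([[0.0, 0.0], [1.0, 1.0]])))

    def test_collinear_cloud(self):
        pts = np.column_stack([np.linspace(0, 10, 20), np.zeros(20)])
        with pytest.raises(DegenerateGeometryError):
            fit_ellipse(PointCloud(pts))

    def test_circle_orientation_tie_break(self):
        fit = fit_ellipse_to_mask(disc_mask(15.0, n=48))
        assert fit.orientation_deg == 0.0


class TestEllipseContains:
    @pytest.fixture
    def ellipse(self):
        return EllipseFit(
            center=(10.0, 5.0), semi_major_mm=4.0, semi_minor_mm=2.0,
            orientation_deg=30.0, aspect_ratio=2.0, eigenvalues=(4.0, 1.0),
        )

    def test_center_inside(self, ellipse):
        assert ellipse_contains(ellipse, (10.0, 5.0))

    def test_boundary_closed_and_just_outside(self, ellipse):
        t = math.radians(30.0)
        on_boundary = (10.0 + 4.0 * math.cos(t), 5.0 + 4.0 * math.sin(t))
        outside = (10.0 + 4.01 * math.cos(t), 5.0 + 4.01 * math.sin(t))
        assert ellipse_contains(ellipse, on_boundary)
        assert not ellipse_contains(ellipse, outside)
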