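"""Rib centroid detection and the closed De Boor B-spline."""

import numpy as np
import pytest

from liverwalker.preprocess import AIR_HU, preprocess_slice
from liverwalker.ribcage import (
    DegenerateCurveError,
    InsufficientCentroidsError,
    RibCentroidSet,
    deboor_point,
    detect_rib_centroids,
    fallback_centroids,
    fit_ribcage_spline,
    mask_inside_ribcage,
    periodic_bspline_setup,
)


def cox_de_boor_basis(i: int, degree: int, t: float, knots: np.ndarray) -> float:
    """Textbook recursive B-spline basis function N_{i,degree}(t)."""
    if degree == 0:
        return 1.0 if knots[i] <= t < knots[i + 1] else 0.0
    left = 0.0
    if knots[i + degree] != knots[i]:
        left = (t - knots[i]) / (knots[i + degree] - knots[i]) * cox_de_boor_basis(i, degree - 1, t, knots)
    right = 0.0
    if knots[i + degree + 1] != knots[i + 1]:
        right = (knots[i + degree + 1] - t) / (knots[i + degree + 1] - knots[i + 1]) * cox_de_boor_basis(
            i + 1, degree - 1, t, knots
        )
    return left + right


class TestDeBoor:
    def test_matches_cox_de_boor_expansion(self):
        """De Boor recursion equals explicit basis-function summation."""
        rng = np.random.default_rng(21)
        for _ in range(5):
            n = int(rng.integers(4, 10))
            pts = rng.uniform(0, 100, (n, 2))
            ctrl, knots = periodic_bspline_setup(pts, degree=3)
            lo, hi = 3, 3 + n
            for t in rng.uniform(lo, hi - 1e-9, 20):
                direct = deboor_point(t, knots, ctrl, 3)
                basis = sum(cox_de_boor_basis(i, 3, t, knots) * ctrl[i] for i in range(len(ctrl)))
                assert np.abs(direct - basis).max() < 1e-9

    def test_closed_curve_periodicity(self):
        pts = np.array([[0, 0], [0, 10], [10, 10], [10, 0]], float)
        ctrl, knots = periodic_bspline_setup(pts, degree=3)
        start = deboor_point(3.0, knots, ctrl, 3)
        end = deboor_point(3.0 + 4 - 1e-12, knots, ctrl, 3)
        assert np.allclose(start, end, atol=1e-6)

    def test_convex_hull_property_on_circle(self):
        angles = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.stack([50 + 30 * np.sin(angles), 50 + 30 * np.cos(angles)], axis=1)
        curve = fit_ribcage_spline(RibCentroidSet(points=pts), shape=(100, 100))
        radii = np.hypot(curve.polyline[:, 0] - 50, curve.polyline[:, 1] - 50)
        assert radii.max() <= 30 + 1e-9  # inside the control-point circle
        assert radii.min() > 20  # but not collapsed


class TestSplineFit:
    def test_square_interior_positive_below_bbox(self):
        pts = np.array([[10, 10], [10, 40], [40, 40], [40, 10]], float)
        curve = fit_ribcage_spline(RibCentroidSet(points=pts), shape=(50, 50))
        assert 0 < curve.interior_area < 30 * 30

    def test_degenerate_collinear_rejected(self):
        pts = np.array([[10, 10], [10, 20], [10, 30], [10, 40]], float)
        with pytest.raises(DegenerateCurveError):
            fit_ribcage_spline(RibCentroidSet(points=pts), shape=(50, 50))

    def test_too_few_centroids_rejected(self):
        with pytest.raises(InsufficientCentroidsError):
            fit_ribcage_spline(RibCentroidSet(points=np.zeros((3, 2))), shape=(10, 10))


class TestCentroidDetection:
    def test_phantom_rib_centroids_within_one_pixel(self, healthy_phantom):
        spec, volume, _ = healthy_phantom
        body, stats, _ = preprocess_slice(volume.voxels[15])
        cents = detect_rib_centroids(stats, body.mask)
        assert cents.count == spec.rib_count
        true = spec.rib_centers()
        for c in cents.points:
            assert min(np.hypot(*(c - t)) for t in true) < 1.0

    def test_no_bone_raises(self):
        slice_hu = np.full((32, 32), 40.0)
        body = np.ones((32, 32), bool)
        with pytest.raises(InsufficientCentroidsError):
            detect_rib_centroids(slice_hu, body)

    def test_touching_ribs_merge_to_one_centroid(self):
        slice_hu = np.full((32, 32), 40.0)
        slice_hu[10:14, 8:12] = 700.0
        slice_hu[10:14, 12:16] = 700.0  # touching: one component
        slice_hu[2:7, 2:7] = 700.0
        slice_hu[2:7, 25:30] = 700.0
        slice_hu[25:30, 2:7] = 700.0
        cents = detect_rib_centroids(slice_hu, np.ones((32, 32), bool))
        assert cents.count == 4  # merged pair counts once

    def test_angular_ordering(self):
        rng = np.random.default_rng(2)
        angles = np.sort(rng.uniform(0, 2 * np.pi, 8))
        pts = np.stack([50 + 20 * np.sin(angles), 50 + 20 * np.cos(angles)], axis=1)
        slice_hu = np.full((100, 100), 40.0)
        for r, c in pts:
            slice_hu[int(r) - 2 : int(r) + 3, int(c) - 2 : int(c) + 3] = 700.0
        cents = detect_rib_centroids(slice_hu, np.ones((100, 100), bool))
        out_angles = np.arctan2(cents.points[:, 0] - 50, cents.points[:, 1] - 50)
        assert (np.diff(out_angles) > 0).all()


class TestMasking:
    def test_interior_kept_exterior_blanked(self):
        angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = np.stack([32 + 20 * np.sin(angles), 32 + 20 * np.cos(angles)], axis=1)
        curve = fit_ribcage_spline(RibCentroidSet(points=pts), shape=(64, 64))
        slice_hu = np.full((64, 64), 40.0)
        masked = mask_inside_ribcage(slice_hu, curve)
        assert masked[32, 32] == 40.0  # body centroid is interior
        assert masked[0, 0] == AIR_HU  # corner is exterior
        assert (masked != AIR_HU).sum() == curve.interior_area


class TestFallback:
    def test_union_of_neighbors(self):
        angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        full = RibCentroidSet(points=np.stack([30 + 20 * np.sin(angles), 30 + 20 * np.cos(angles)], axis=1))
        merged = fallback_centroids([full, full])
        assert merged.count >= 8

    def test_no_neighbors_raises(self):
        with pytest.raises(InsufficientCentroidsError):
            fallback_centroids([None, None])

    def test_rib_poor_slice_recovers_interior_area(self):
        """A slice with 3 ribs falls back to its neighbours' centroids and
        keeps a comparable ribcage interior."""
        from liverwalker.phantom import generate_phantom, make_test_suite
        from liverwalker.pipeline import PipelineConfig, _RibcageMasker

        spec = make_test_suite("rib-poor-slice", shape=(40, 256, 256))
        volume, _, spec = generate_phantom(spec)
        z = spec.rib_poor_slices[0]
        bodies, stats = [], []
        for zz in (z - 1, z, z + 1):
            body, st, _ = preprocess_slice(volume.voxels[zz])
            bodies.append(body)
            stats.append(st)
        masker = _RibcageMasker(np.stack(stats), bodies, PipelineConfig())
        prev_curve, _ = masker.curve(0)
        poor_curve, used_fb = masker.curve(1, prev_area=prev_curve.interior_area)
        assert used_fb
        assert poor_curve.interior_area >= 0.8 * prev_curve.interior_area
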