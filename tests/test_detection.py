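"""Sphere solvers, RANSAC detection, overlap geometry and suppression."""

import itertools

import numpy as np
import pytest
from scipy.optimize import least_squares

from bunch3d import (DetectionParams, SphereModel, detect_berries_in_region,
                     fit_sphere_least_squares, fit_sphere_minimal,
                     ransac_sphere, resolve_overlaps, sphere_overlap_fraction)

from conftest import assert_model_valid, sample_sphere


def geometric_sphere_fit(points, x0):
    """Independent oracle: nonlinear least squares on the geometric residual
    ||p - c|| - r."""
    def resid(x):
        return np.linalg.norm(points - x[:3], axis=1) - x[3]
    sol = least_squares(resid, x0).x
    return sol[:3], sol[3]


def _sphere(center, radius, n_inliers=0):
    return SphereModel(center=center, radius=radius,
                       inlier_indices=np.arange(n_inliers))


class TestMinimalFit:
    def test_unit_sphere_from_any_nondegenerate_quadruple(self):
        octa = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        for quad in itertools.combinations(octa, 4):
            result = fit_sphere_minimal(*quad)
            if result is None:       # coplanar quadruples of the octahedron
                continue
            center, radius = result
            np.testing.assert_allclose(center, 0, atol=1e-12)
            assert radius == pytest.approx(1.0, abs=1e-12)

    def test_coplanar_is_degenerate(self):
        assert fit_sphere_minimal((0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)) is None

    def test_recovers_random_sphere(self, rng):
        truth_c, truth_r = np.array([3.0, -2.0, 7.0]), 8.5
        pts = sample_sphere(rng, truth_c, truth_r, 4)
        center, radius = fit_sphere_minimal(*pts)
        np.testing.assert_allclose(center, truth_c, atol=1e-9)
        assert radius == pytest.approx(truth_r, abs=1e-9)


class TestLeastSquaresFit:
    def test_exact_on_noiseless_samples(self, rng):
        pts = sample_sphere(rng, [1, 2, 3], 6.0, 500)
        center, radius = fit_sphere_least_squares(pts)
        np.testing.assert_allclose(center, [1, 2, 3], atol=1e-9)
        assert radius == pytest.approx(6.0, abs=1e-9)

    def test_hemisphere_stays_full_rank(self, rng):
        pts = sample_sphere(rng, [0, 0, 0], 7.0, 2000)
        pts = pts[pts[:, 2] > 0]      # partial-scan case: one side only
        center, radius = fit_sphere_least_squares(pts)
        np.testing.assert_allclose(center, 0, atol=1e-6)
        assert radius == pytest.approx(7.0, abs=1e-6)

    def test_noisy_fit_matches_geometric_oracle(self, rng):
        pts = sample_sphere(rng, [0, 0, 0], 8.0, 5000, noise=0.1)
        center, radius = fit_sphere_least_squares(pts)
        assert radius == pytest.approx(8.0, abs=0.05)
        oc, orr = geometric_sphere_fit(pts, np.array([0.0, 0, 0, 7.5]))
        np.testing.assert_allclose(center, oc, atol=0.02)
        assert radius == pytest.approx(orr, abs=0.02)

    def test_coplanar_degenerate(self, rng):
        pts = np.column_stack([rng.normal(size=(50, 2)), np.zeros(50)])
        assert fit_sphere_least_squares(pts) is None


class TestRansac:
    def test_perfect_data(self, rng):
        pts = sample_sphere(rng, [10, 5, -2], 5.0, 2000)
        model = ransac_sphere(pts, DetectionParams(), rng)
        assert model is not None
        assert model.radius == pytest.approx(5.0, abs=1e-6)
        assert model.n_inliers >= 1999

    def test_radius_below_gate_rejected(self, rng):
        pts = sample_sphere(rng, [0, 0, 0], 0.5, 2000)
        assert ransac_sphere(pts, DetectionParams(), rng) is None

    def test_radius_above_gate_rejected(self, rng):
        pts = sample_sphere(rng, [0, 0, 0], 20.0, 2000)
        assert ransac_sphere(pts, DetectionParams(), rng) is None

    def test_insufficient_supporters_rejected(self, rng):
        pts = sample_sphere(rng, [0, 0, 0], 5.0, 99)
        assert ransac_sphere(pts, DetectionParams(), rng) is None

    def test_robust_to_clutter(self, rng):
        # a berry inside a larger region patch: 70% surface, 30% scatter
        sphere_pts = sample_sphere(rng, [0, 0, 0], 5.0, 1400)
        clutter = rng.uniform(-15, 15, (600, 3))
        pts = np.vstack([sphere_pts, clutter])
        params = DetectionParams()
        model = ransac_sphere(pts, params, rng)
        assert model is not None
        assert model.radius == pytest.approx(5.0, abs=0.1)
        clutter_in = (model.inlier_indices >= 1400).sum()
        assert clutter_in <= 0.05 * 600
        assert_model_valid(model, pts, params)

    def test_deterministic_under_seed(self, rng):
        pts = np.vstack([sample_sphere(rng, [0, 0, 0], 5.0, 1000, noise=0.1),
                         rng.uniform(-10, 10, (200, 3))])
        params = DetectionParams()
        m1 = ransac_sphere(pts, params, np.random.default_rng(7))
        m2 = ransac_sphere(pts, params, np.random.default_rng(7))
        np.testing.assert_array_equal(m1.center, m2.center)
        assert m1.radius == m2.radius
        np.testing.assert_array_equal(m1.inlier_indices, m2.inlier_indices)

    def test_matches_least_squares_oracle_on_clean_sphere(self, rng):
        pts = sample_sphere(rng, [2, -1, 4], 6.5, 1500)
        model = ransac_sphere(pts, DetectionParams(), rng)
        center, radius = fit_sphere_least_squares(pts)
        np.testing.assert_allclose(model.center, center, atol=1e-6)
        assert model.radius == pytest.approx(radius, abs=1e-6)


class TestIterativeRegionDetection:
    def test_undersegmented_region_yields_both_berries(self, rng):
        pts = np.vstack([sample_sphere(rng, [0, 0, 0], 6.0, 1200),
                         sample_sphere(rng, [30, 0, 0], 8.0, 1500)])
        models = detect_berries_in_region(pts, DetectionParams(), rng)
        assert len(models) == 2
        assert sorted(round(m.radius, 1) for m in models) == [6.0, 8.0]

    def test_inlier_sets_disjoint(self, rng):
        pts = np.vstack([sample_sphere(rng, [0, 0, 0], 6.0, 1200),
                         sample_sphere(rng, [14, 0, 0], 6.0, 1200)])
        models = detect_berries_in_region(pts, DetectionParams(), rng)
        all_inliers = np.concatenate([m.inlier_indices for m in models])
        assert len(np.unique(all_inliers)) == len(all_inliers)

    def test_small_region_empty(self, rng):
        pts = sample_sphere(rng, [0, 0, 0], 5.0, 80)
        assert detect_berries_in_region(pts, DetectionParams(), rng) == []

    def test_pure_noise_empty(self, rng):
        pts = rng.uniform(0, 40, (500, 3))
        assert detect_berries_in_region(pts, DetectionParams(), rng) == []


class TestOverlapFraction:
    def test_identical_spheres(self):
        assert sphere_overlap_fraction(_sphere([0, 0, 0], 3), _sphere([0, 0, 0], 3)) == 1.0

    def test_containment(self):
        assert sphere_overlap_fraction(_sphere([0, 0, 0], 8), _sphere([1, 0, 0], 2)) == 1.0

    def test_tangent_and_disjoint(self):
        assert sphere_overlap_fraction(_sphere([0, 0, 0], 1), _sphere([2, 0, 0], 1)) == 0.0
        assert sphere_overlap_fraction(_sphere([0, 0, 0], 1), _sphere([5, 0, 0], 1)) == 0.0

    def test_unit_spheres_at_unit_distance(self):
        f = sphere_overlap_fraction(_sphere([0, 0, 0], 1), _sphere([1, 0, 0], 1))
        assert f == pytest.approx(5.0 / 16.0, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(20):
            s1 = _sphere(rng.uniform(-5, 5, 3), rng.uniform(1, 9))
            s2 = _sphere(rng.uniform(-5, 5, 3), rng.uniform(1, 9))
            f12 = sphere_overlap_fraction(s1, s2)
            assert f12 == pytest.approx(sphere_overlap_fraction(s2, s1), abs=1e-14)
            assert 0.0 <= f12 <= 1.0

    def test_against_monte_carlo(self, rng):
        # small-sample version of the closed-form vs MC cross-check
        s1 = _sphere([0, 0, 0], 4.0)
        s2 = _sphere([3.0, 1.0, 0.5], 3.0)
        u = rng.normal(size=(1_000_000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = 3.0 * rng.uniform(size=1_000_000) ** (1 / 3)
        inside_small = np.asarray(s2.center) + u * r[:, None]
        mc = (np.linalg.norm(inside_small - np.asarray(s1.center), axis=1) <= 4.0).mean()
        assert sphere_overlap_fraction(s1, s2) == pytest.approx(mc, abs=3e-3)


class TestResolveOverlaps:
    def test_duplicate_collapses_to_most_supported(self):
        strong = _sphere([0, 0, 0], 5, n_inliers=500)
        weak = _sphere([0.2, 0, 0], 5, n_inliers=300)
        assert resolve_overlaps([weak, strong]) == [strong]

    def test_low_overlap_pair_survives(self):
        # r=1 spheres at d=1.8: overlap 0.0725 < 0.25
        a = _sphere([0, 0, 0], 1, n_inliers=400)
        b = _sphere([1.8, 0, 0], 1, n_inliers=300)
        assert sphere_overlap_fraction(a, b) < 0.25
        assert resolve_overlaps([a, b]) == [a, b]

    def test_chain_keeps_only_best(self):
        # A-B and B-C overlap heavily, A-C barely: greedy keeps just B
        a = _sphere([0.0, 0, 0], 1, n_inliers=300)
        b = _sphere([0.8, 0, 0], 1, n_inliers=400)
        c = _sphere([1.6, 0, 0], 1, n_inliers=350)
        assert sphere_overlap_fraction(a, b) > 0.25
        assert sphere_overlap_fraction(b, c) > 0.25
        assert sphere_overlap_fraction(a, c) < 0.25
        assert resolve_overlaps([a, b, c]) == [b]

    def test_accepted_pairs_below_threshold(self, rng):
        models = [_sphere(rng.uniform(0, 20, 3), rng.uniform(2, 8),
                          n_inliers=int(rng.integers(100, 1000))) for _ in range(30)]
        kept = resolve_overlaps(models, 0.25)
        for m1, m2 in itertools.combinations(kept, 2):
            assert sphere_overlap_fraction(m1, m2) <= 0.25

    def test_empty(self):
        assert resolve_overlaps([]) == []


def test_diagnostic_sphere_export_readable(tmp_path, rng):
    from bunch3d import read_ply
    from bunch3d.detection import export_spheres_ply
    models = [_sphere([0, 0, 0], 5, 100), _sphere([20, 0, 0], 7, 100)]
    path = tmp_path / "spheres.ply"
    export_spheres_ply(models, path, points_per_sphere=50)
    cloud = read_ply(path)
    assert len(cloud) == 100
    np.testing.assert_array_equal(cloud.colors[0], [0, 200, 0])


def test_param_validation():
    with pytest.raises(ValueError):
        DetectionParams(min_radius=0)
    with pytest.raises(ValueError):
        DetectionParams(min_radius=5, max_radius=3)
    with pytest.raises(ValueError):
        DetectionParams(min_supporters=3)
    with pytest.raises(ValueError):
        DetectionParams(overlap_threshold=1.5)
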