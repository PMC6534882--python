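import numpy as np
import pytest
from scipy import ndimage

from maacs.metrics import overlap_metrics
from maacs.snake import (
    PotentialField,
    SnakeParams,
    build_potential,
    contour_to_mask,
    evolve,
    internal_energy,
    total_energy,
)
from maacs.template import InitialActiveContour, IntensityPrior


def circle(center, radius, n):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.sin(th),
                            center[1] + radius * np.cos(th)])


def disk_image(shape=(96, 96), center=(47.5, 47.5), radius=25.0, blur=1.0):
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    disk = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= radius**2
    return ndimage.gaussian_filter(np.where(disk, 0.9, 0.1), blur), disk


class TestBuildPotential:
    def test_constant_image_uninformative_prior_zero_force(self):
        img = np.full((16, 16), 0.5)
        prior = IntensityPrior(counts=np.ones(20))  # weights all 1
        field = build_potential(img, prior)
        np.testing.assert_allclose(field.force_r, 0.0, atol=1e-12)
        np.testing.assert_allclose(field.force_c, 0.0, atol=1e-12)
        assert np.ptp(field.energy) == pytest.approx(0.0, abs=1e-12)

    def test_step_edge_attracts_from_both_sides(self):
        img = np.full((20, 20), 0.2)
        img[:, 10:] = 0.8
        field = build_potential(img, prior=None, sigma=1.0)
        # left of the edge the force should point right (+c), and vice versa
        assert field.force_c[10, 7] > 0
        assert field.force_c[10, 12] < 0

    def test_prior_stripe_raises_potential_additively(self):
        img = np.full((20, 20), 0.3)
        img[:, 8:12] = 0.625  # stripe at the modal bin center, flat inside
        counts = np.zeros(20)
        counts[12] = 10  # modal bin covers 0.60-0.65
        counts[0] = 1
        prior = IntensityPrior(counts=counts)
        with_prior = build_potential(img, prior, sigma=0.5)
        without = build_potential(img, None, sigma=0.5)
        assert (with_prior.energy[10, 10] - without.energy[10, 10]) == pytest.approx(
            1.0, abs=0.05
        )

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            build_potential(np.zeros((8, 8)), sigma=0.0)


class TestInternalEnergy:
    def test_regular_polygon_matches_closed_form(self):
        # elasticity of a regular n-gon of radius r: 1/2 * alpha * n * (2 r sin(pi/n))^2
        for n in (16, 64, 256):
            r = 10.0
            e = internal_energy(circle((0, 0), r, n), alpha=2.0, beta=0.0)
            expected = 0.5 * 2.0 * n * (2 * r * np.sin(np.pi / n)) ** 2
            assert e == pytest.approx(expected, rel=1e-9)
        # refinement: as n grows the polygon energy approaches the circle
        # limit alpha * 2 pi^2 r^2 / n * ... -> per-point energy shrinks as 1/n^2
        e64 = internal_energy(circle((0, 0), 10, 64), 1.0, 0.0)
        e128 = internal_energy(circle((0, 0), 10, 128), 1.0, 0.0)
        assert e128 / e64 == pytest.approx(0.5, rel=1e-3)

    def test_collinear_points_have_zero_bending(self):
        # a closed 'flat' rectangle degenerated to a line has bending only at
        # the two turns; interior collinear runs contribute nothing
        pts = np.array([[0.0, c] for c in range(8)] + [[0.0, c] for c in range(7, -1, -1)])
        e_interior = internal_energy(pts, alpha=0.0, beta=1.0)
        # only the fold points carry curvature
        d2 = np.roll(pts, -1, axis=0) - 2 * pts + np.roll(pts, 1, axis=0)
        assert e_interior == pytest.approx(0.5 * (d2**2).sum())

    def test_scaling_homogeneity(self, rng):
        pts = rng.random((12, 2)) * 10
        assert internal_energy(2 * pts, 1.0, 1.0) == pytest.approx(
            4 * internal_energy(pts, 1.0, 1.0)
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            internal_energy(np.zeros((3, 2)), 1.0, 1.0)


class TestEvolve:
    def test_elasticity_only_circle_shrinks_monotonically(self):
        field = PotentialField(energy=np.zeros((64, 64)),
                               force_r=np.zeros((64, 64)), force_c=np.zeros((64, 64)))
        init = circle((31.5, 31.5), 20.0, 48)
        params = SnakeParams(alpha=10.0, beta=0.0, gamma=0.0, step_size=0.01,
                             max_iters=50, resample_every=0, min_evolve_area=0)
        state = evolve(InitialActiveContour(loops=[init]), field, params)
        radii = np.linalg.norm(state.loops[0] - [31.5, 31.5], axis=1)
        assert radii.mean() < 20.0
        # energy trace strictly non-increasing
        seg = state.energy_trace[0][0]
        assert np.all(np.diff(seg) <= 1e-9)

    def test_zero_force_zero_internal_is_fixed_point(self):
        field = PotentialField(energy=np.zeros((32, 32)),
                               force_r=np.zeros((32, 32)), force_c=np.zeros((32, 32)))
        init = circle((15.5, 15.5), 8.0, 24)
        params = SnakeParams(alpha=0.0, beta=0.0, gamma=0.0, max_iters=20,
                             resample_every=0, min_evolve_area=0)
        state = evolve(InitialActiveContour(loops=[init]), field, params)
        np.testing.assert_array_equal(state.loops[0], init)

    def test_disk_phantom_convergence(self):
        """Circle 3 px outside a high-contrast disk converges onto its boundary."""
        img, disk = disk_image()
        field = build_potential(img, prior=None, sigma=2.0)
        init = circle((47.5, 47.5), 28.0, 120)
        params = SnakeParams(alpha=10, beta=40, gamma=500, max_iters=800, tol=0.02)
        state = evolve(InitialActiveContour(loops=[init]), field, params)
        mask = contour_to_mask(state, img.shape)
        dice = overlap_metrics(disk.astype(int), mask.astype(int), 1)[0]
        radial_err = np.abs(
            np.linalg.norm(state.loops[0] - [47.5, 47.5], axis=1) - 25.0
        ).mean()
        assert dice >= 0.95
        assert radial_err <= 1.0
        # discrete energy non-increasing within every segment
        for loop_trace in state.energy_trace:
            for seg in loop_trace:
                assert np.all(np.diff(seg) <= 1e-6)

    def test_deterministic_bit_identical(self):
        img, _ = disk_image()
        field = build_potential(img, prior=None, sigma=2.0)
        init = circle((47.5, 47.5), 28.0, 60)
        params = SnakeParams(alpha=10, beta=40, gamma=500, max_iters=100)
        s1 = evolve(InitialActiveContour(loops=[init]), field, params)
        s2 = evolve(InitialActiveContour(loops=[init]), field, params)
        np.testing.assert_array_equal(s1.loops[0], s2.loops[0])
        assert s1.energy == s2.energy

    def test_point_count_preserved(self):
        img, _ = disk_image()
        field = build_potential(img, prior=None, sigma=2.0)
        init = circle((47.5, 47.5), 28.0, 77)
        state = evolve(InitialActiveContour(loops=[init]), field,
                       SnakeParams(alpha=10, beta=40, gamma=500, max_iters=60))
        assert len(state.loops[0]) == 77

    def test_sub_resolution_loop_passes_through(self):
        img, _ = disk_image()
        field = build_potential(img, prior=None, sigma=2.0)
        tiny = circle((10.0, 10.0), 1.5, 16)
        state = evolve(InitialActiveContour(loops=[tiny]), field, SnakeParams())
        np.testing.assert_array_equal(state.loops[0], tiny)


class TestContourToMask:
    def test_axis_aligned_square_fills_36_pixels(self):
        loop = np.array([[2.0, 2.0], [2.0, 7.0], [7.0, 7.0], [7.0, 2.0]])
        mask = contour_to_mask([loop], (10, 10))
        assert mask.sum() == 36
        assert mask[2:8, 2:8].all()

    def test_degenerate_loop_is_empty_and_flagged(self):
        tiny = np.array([[5.0, 5.0], [5.0, 5.3], [5.3, 5.3], [5.3, 5.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            mask = contour_to_mask([tiny], (10, 10))
        assert not mask.any()

    def test_two_disjoint_loops_sum(self):
        a = np.array([[1.0, 1.0], [1.0, 4.0], [4.0, 4.0], [4.0, 1.0]])
        b = np.array([[10.0, 10.0], [10.0, 13.0], [13.0, 13.0], [13.0, 10.0]])
        both = contour_to_mask([a, b], (16, 16))
        assert both.sum() == contour_to_mask([a], (16, 16)).sum() + contour_to_mask(
            [b], (16, 16)
        ).sum()

    def test_matches_shapely_oracle_on_random_star_polygon(self, rng):
        from shapely.geometry import Point, Polygon

        th = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        radii = 6 + 3 * rng.random(24)
        loop = np.column_stack([15 + radii * np.sin(th), 15 + radii * np.cos(th)])
        mask = contour_to_mask([loop], (30, 30))
        poly = Polygon([(r, c) for r, c in loop])
        oracle = np.zeros((30, 30), dtype=bool)
        for r in range(30):
            for c in range(30):
                oracle[r, c] = poly.covers(Point(r, c))
        np.testing.assert_array_equal(mask, oracle)


def test_total_energy_combines_internal_and_external():
    field = PotentialField(energy=np.ones((16, 16)),
                           force_r=np.zeros((16, 16)), force_c=np.zeros((16, 16)))
    loop = circle((7.5, 7.5), 4.0, 12)
    p = SnakeParams(alpha=1.0, beta=0.0, gamma=2.0)
    expected = internal_energy(loop, 1.0, 0.0) - 2.0 * 12
    assert total_energy(loop, field, p) == pytest.approx(expected)
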