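import numpy as np
import pytest

from maacs.fusion import InitialTemplate
from maacs.template import (
    ContourPointSet,
    IntensityPrior,
    boundary_mask,
    build_intensity_prior,
    chain_contour,
    extract_template_contour,
    moore_trace,
    resample_closed,
    score_candidates,
    search_area_mask,
    set_search_areas,
    smooth_closed,
)


class TestIntensityPrior:
    def test_toy_three_bin_worked_example(self):
        """counts [10, 30, 60] -> pr [0.1, 0.3, 0.6], weights [0, 0.4, 1]."""
        prior = IntensityPrior(counts=[10, 30, 60])
        np.testing.assert_allclose(prior.pr, [0.1, 0.3, 0.6])
        np.testing.assert_allclose(prior.weights, [0.0, 0.4, 1.0])

    def test_all_equal_counts_give_uninformative_prior(self):
        prior = IntensityPrior(counts=[5, 5, 5, 5])
        np.testing.assert_allclose(prior.weights, 1.0)

    def test_modal_and_empty_bin_endpoints(self):
        prior = IntensityPrior(counts=[0, 3, 9, 1])
        assert prior.weights[2] == 1.0  # modal bin
        assert prior.weights[0] == 0.0  # empty bin

    def test_pr_sums_to_one(self):
        prior = IntensityPrior(counts=[1, 2, 3, 4])
        assert prior.pr.sum() == pytest.approx(1.0)

    def test_bin_lookup_of_values(self):
        prior = IntensityPrior(counts=[1, 2, 3, 4])  # bins of width 0.25
        np.testing.assert_array_equal(prior.bin_of(np.array([0.0, 0.3, 0.9, 1.0])),
                                      [0, 1, 3, 3])

    def test_smooth_lookup_interpolates_between_bin_centers(self):
        prior = IntensityPrior(counts=[0, 10, 0])
        # bin centers at 1/6, 1/2, 5/6 with weights 0, 1, 0
        assert prior.weight_of(np.array([1 / 3]), smooth=True)[0] == pytest.approx(0.5)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            IntensityPrior(counts=[0, 0, 0])
        with pytest.raises(ValueError):
            IntensityPrior(counts=[-1, 2])

    def test_built_from_atlases_peaks_at_edge_intensity(self, default_suite):
        from maacs.imageio import Atlas, normalize_intensity

        atlases = [
            Atlas(intensity=normalize_intensity(a.intensity), label=a.label, id=a.id)
            for a in default_suite.atlases
        ]
        prior = build_intensity_prior(atlases, target_class=2)
        mode_center = prior.bin_edges[np.argmax(prior.weights)] + 0.025
        # the contour runs between surround and inner intensity; its modal
        # value must lie strictly between them
        assert 0.45 < mode_center < 0.85

    def test_missing_class_raises(self, default_suite):
        with pytest.raises(ValueError):
            build_intensity_prior(default_suite.atlases, target_class=99)


class TestTemplateContour:
    def test_three_by_three_square_has_ring_boundary(self):
        mask = np.zeros((5, 5), dtype=np.int32)
        mask[1:4, 1:4] = 1
        pts = extract_template_contour(InitialTemplate(prob=mask.astype(float),
                                                       binary=mask, target_class=1))
        assert len(pts) == 8  # all but the center pixel
        assert (2, 2) not in {tuple(p) for p in pts}

    def test_single_pixel_is_its_own_contour(self):
        mask = np.zeros((4, 4), dtype=np.int32)
        mask[2, 1] = 1
        pts = extract_template_contour(mask)
        assert {tuple(p) for p in pts} == {(2, 1)}

    def test_five_by_five_square_has_16_perimeter_pixels(self):
        mask = np.zeros((9, 9), dtype=np.int32)
        mask[2:7, 2:7] = 1
        pts = extract_template_contour(mask)
        assert len(pts) == 16

    def test_empty_template_raises(self):
        with pytest.raises(ValueError):
            extract_template_contour(np.zeros((4, 4), dtype=np.int32))


class TestSearchAreas:
    def test_isolated_pixel_gets_full_square(self):
        areas = set_search_areas(np.array([[20, 20]]), 8, shape=(40, 40))
        a = areas[0]
        assert (a.left, a.right, a.up, a.down) == (8, 8, 8, 8)

    def test_second_contour_line_clips_to_midpoint(self):
        # second contour pixel 6 px away in +x (columns) -> right extent 3
        contour = np.array([[20, 20], [20, 26]])
        a = next(x for x in set_search_areas(contour, 8, shape=(40, 40))
                 if (x.row, x.col) == (20, 20))
        assert a.right == 3
        assert (a.left, a.up, a.down) == (8, 8, 8)

    def test_adjacent_contour_pixel_is_exempt(self):
        contour = np.array([[20, 20], [19, 20]])  # 8-adjacent in +y
        a = next(x for x in set_search_areas(contour, 8, shape=(40, 40))
                 if (x.row, x.col) == (20, 20))
        assert a.up == 8

    def test_extents_clipped_at_image_frame(self):
        a = set_search_areas(np.array([[1, 1]]), 8, shape=(40, 40))[0]
        assert (a.left, a.up) == (1, 1)

    def test_clipping_never_grows_areas(self, rng):
        pts = rng.integers(5, 35, size=(15, 2))
        clipped = set_search_areas(pts, 8, shape=(40, 40))
        for a in clipped:
            assert max(a.left, a.right, a.up, a.down) <= 8


class TestScoreCandidates:
    @staticmethod
    def _edge_image(shape=(32, 32), col=16):
        img = np.full(shape, 0.2)
        img[:, col:] = 0.8
        return img

    def test_scores_match_independent_formula(self):
        img = self._edge_image()
        prior = IntensityPrior(counts=np.ones(20))  # uninformative: P == 1
        contour = np.array([[r, 16] for r in range(10, 22)])
        areas = set_search_areas(contour, 4, shape=img.shape)
        out = score_candidates(img, areas, prior, w_p=0.7, w_g=0.3, threshold=0.6)
        # independent check at each accepted point: Y = 0.7*1 + 0.3*gn >= 0.6
        assert len(out.points) > 0
        assert np.all(out.scores >= 0.6)
        assert np.nanmax(out.score_image) <= 1.0 + 1e-12
        assert np.nanmin(out.score_image) >= 0.0

    def test_flat_region_with_modal_intensity_scores_w_p(self):
        img = np.full((24, 24), 0.52)  # all pixels in bin 10
        counts = np.zeros(20)
        counts[10] = 5
        counts[0] = 1  # ensure min-max is defined with weight 1 at bin 10
        prior = IntensityPrior(counts=counts)
        areas = set_search_areas(np.array([[12, 12]]), 4, shape=img.shape)
        out = score_candidates(img, areas, prior, w_p=0.7, w_g=0.3, threshold=0.6)
        # zero gradient everywhere -> grad_norm 0 -> Y = w_p = 0.7, accepted
        np.testing.assert_allclose(out.scores, 0.7)
        assert len(out.points) == 9 * 9

    def test_mid_score_rejected_at_threshold(self):
        img = np.full((24, 24), 0.52)
        counts = np.zeros(20)
        counts[10] = 5
        counts[0] = 1
        prior = IntensityPrior(counts=counts)
        areas = set_search_areas(np.array([[12, 12]]), 4, shape=img.shape)
        # w_p = 0.5 -> Y = 0.5 < 0.6 everywhere -> nothing accepted
        out = score_candidates(img, areas, prior, w_p=0.5, w_g=0.5, threshold=0.6)
        assert len(out.points) == 0

    def test_weights_must_sum_to_one(self, rng):
        with pytest.raises(ValueError):
            score_candidates(rng.random((8, 8)), [], IntensityPrior(counts=[1, 2]),
                             w_p=0.7, w_g=0.7)

    def test_empty_area_union_raises(self, rng):
        with pytest.raises(ValueError):
            score_candidates(rng.random((8, 8)), [], IntensityPrior(counts=[1, 2]))


class TestMooreTrace:
    def test_five_by_five_square_boundary_order(self):
        comp = np.zeros((9, 9), dtype=bool)
        comp[2:7, 2:7] = True
        trace = moore_trace(comp)
        assert len(trace) == 16
        pts = [tuple(p) for p in trace]
        assert len(set(pts)) == 16
        # consecutive boundary pixels (cyclically) are 8-adjacent
        for i in range(16):
            d = np.abs(np.array(pts[i]) - np.array(pts[(i + 1) % 16]))
            assert d.max() == 1
        # every perimeter pixel is visited
        perimeter = {(r, c) for r in range(2, 7) for c in range(2, 7)
                     if r in (2, 6) or c in (2, 6)}
        assert set(pts) == perimeter

    def test_single_pixel(self):
        comp = np.zeros((3, 3), dtype=bool)
        comp[1, 1] = True
        np.testing.assert_array_equal(moore_trace(comp), [[1, 1]])

    def test_empty_component_raises(self):
        with pytest.raises(ValueError):
            moore_trace(np.zeros((3, 3), dtype=bool))


class TestChainContour:
    @staticmethod
    def _ring_points(c, r, n=64):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.unique(np.round(np.column_stack([c[0] + r * np.sin(th),
                                                  c[1] + r * np.cos(th)])).astype(int),
                        axis=0)
        return pts

    def test_square_perimeter_chains_into_one_loop(self):
        pts = np.array([(r, c) for r in range(10, 15) for c in range(10, 15)
                        if r in (10, 14) or c in (10, 14)])
        iac = chain_contour(pts, (25, 25))
        assert len(iac.loops) == 1
        loop = iac.loops[0]
        assert len(loop) >= 16
        # the loop encloses the square's interior
        from maacs.snake import contour_to_mask
        mask = contour_to_mask([loop], (25, 25))
        assert mask[12, 12]

    def test_two_disjoint_rings_give_two_loops(self):
        pts = np.vstack([self._ring_points((15, 15), 6), self._ring_points((40, 40), 6)])
        iac = chain_contour(pts, (55, 55))
        assert len(iac.loops) == 2

    def test_one_pixel_gap_is_closed(self):
        pts = self._ring_points((15, 15), 7)
        # knock out a single pixel to open a 1-px gap
        pts = pts[~((pts[:, 0] == 8) & (pts[:, 1] == 15))]
        iac = chain_contour(pts, (31, 31))
        assert len(iac.loops) == 1
        from maacs.snake import contour_to_mask
        assert contour_to_mask(iac, (31, 31))[15, 15]

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            chain_contour(np.array([[2, 2], [3, 3]]), (8, 8))

    def test_loops_are_closed_and_simple(self):
        pts = self._ring_points((20, 20), 10)
        loop = chain_contour(pts, (41, 41)).loops[0]
        # no consecutive-segment self-intersection: check all segment pairs
        segs = list(zip(loop, np.roll(loop, -1, axis=0)))

        def intersects(p, q, a, b):
            def cross(o, u, v):
                return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])
            return (cross(p, q, a) * cross(p, q, b) < 0
                    and cross(a, b, p) * cross(a, b, q) < 0)

        n = len(segs)
        for i in range(n):
            for j in range(i + 2, n):
                if i == 0 and j == n - 1:
                    continue
                assert not intersects(*segs[i], *segs[j])


class TestResampling:
    def test_uniform_arc_length_spacing(self):
        square = np.array([[0.0, 0.0], [0.0, 9.0], [9.0, 9.0], [9.0, 0.0]])
        out = resample_closed(square, 36)
        seg = np.linalg.norm(np.diff(np.vstack([out, out[:1]]), axis=0), axis=1)
        np.testing.assert_allclose(seg, 1.0, atol=1e-9)

    def test_smooth_closed_preserves_point_count_and_centroid(self, rng):
        th = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        loop = np.column_stack([10 + 5 * np.sin(th), 10 + 5 * np.cos(th)])
        loop += rng.normal(0, 0.3, size=loop.shape)
        out = smooth_closed(loop, 5)
        assert out.shape == loop.shape
        np.testing.assert_allclose(out.mean(axis=0), loop.mean(axis=0), atol=1e-9)


def test_boundary_mask_interior_excluded():
    mask = np.zeros((7, 7), dtype=bool)
    mask[1:6, 1:6] = True
    b = boundary_mask(mask)
    assert b[1, 1] and not b[3, 3]
    assert b.sum() == 16
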