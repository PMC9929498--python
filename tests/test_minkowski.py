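"""Threshold sweep and the three Minkowski measures, against independent
oracles: pixel counting, boundary-edge counting, analytic geometry, and
flood-fill component/hole labelling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from minkpat import (
    IntensityImage,
    area,
    euler_characteristic,
    integrate_functional,
    minkowski_curve,
    p2_over_a,
    perimeter,
    threshold_sweep,
)
from minkpat.minkowski import sweep_levels

from conftest import digital_disc, flood_fill_euler, square_mask


class TestThresholdSweep:
    def test_two_level_image_every_slice_is_the_marking_mask(self, two_level_image):
        marking = two_level_image.pixels == 1.0
        slices = threshold_sweep(two_level_image, n_levels=80)
        assert len(slices) == 80
        for b in slices:
            np.testing.assert_array_equal(b.pixels, marking)

    def test_constant_image_gives_empty_slices(self):
        img = IntensityImage(pixels=np.zeros((10, 10)))
        slices = threshold_sweep(img, n_levels=80)
        assert all(b.pixels.sum() == 0 for b in slices)

    def test_levels_strictly_interior(self, two_level_image):
        lv = sweep_levels(two_level_image, 80)
        assert lv.min() > 0.0 and lv.max() < 1.0
        np.testing.assert_allclose(np.diff(lv), lv[1] - lv[0])

    def test_three_level_image_matches_grid_enumeration_oracle(self):
        px = np.zeros((12, 12))
        px[:4] = 0.5
        px[4:6] = 1.0
        img = IntensityImage(pixels=px)
        slices = threshold_sweep(img, n_levels=80)
        areas = np.array([b.pixels.sum() for b in slices])
        # oracle: strict > comparison of each pixel value against each level
        levels = sweep_levels(img, 80)
        expected = np.array([(px > lv).sum() for lv in levels])
        np.testing.assert_array_equal(areas, expected)
        # A steps down once near 0.5: levels below 0.5 retain both upper values
        n_large = int((levels < 0.5).sum())
        assert (areas == (px > 0.4).sum()).sum() == n_large

    def test_invalid_level_count(self, two_level_image):
        with pytest.raises(ValueError):
            threshold_sweep(two_level_image, n_levels=0)


class TestArea:
    def test_full_and_empty(self):
        assert area(np.ones((5, 5), bool)) == 25
        assert area(np.zeros((5, 5), bool)) == 0

    def test_random_image_equals_loop_count(self, rng):
        f = rng.random((64, 64)) > 0.6
        naive = sum(1 for v in f.ravel() if v)
        assert area(f) == naive


class TestPerimeter:
    def test_empty_is_zero_both_methods(self):
        f = np.zeros((8, 8), bool)
        assert perimeter(f, "crofton4") == 0.0
        assert perimeter(f, "boundary_edges") == 0.0

    @pytest.mark.parametrize("side", [1, 3, 10, 25])
    def test_square_boundary_edges_exactly_4n(self, side):
        assert perimeter(square_mask(side), "boundary_edges") == 4 * side

    @pytest.mark.parametrize("side", [10, 20, 40])
    def test_square_crofton_within_15_percent(self, side):
        est = perimeter(square_mask(side), "crofton4")
        assert est == pytest.approx(4 * side, rel=0.15)

    def test_disc_crofton_within_5_percent_of_circumference(self):
        est = perimeter(digital_disc(25), "crofton4")
        assert est == pytest.approx(2 * np.pi * 25, rel=0.05)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            perimeter(np.ones((3, 3), bool), "hexagonal")


class TestEulerCharacteristic:
    def test_filled_square_is_one(self):
        assert euler_characteristic(square_mask(3)) == 1

    def test_ring_is_zero(self):
        ring = square_mask(3)
        ring[4, 4] = False  # knock out the centre -> one hole
        assert euler_characteristic(ring) == 0

    def test_two_disjoint_squares(self):
        f = np.zeros((10, 16), bool)
        f[2:5, 2:5] = True
        f[2:5, 9:12] = True
        assert euler_characteristic(f) == 2

    def test_diagonal_pair_depends_on_connectivity(self):
        f = np.zeros((4, 4), bool)
        f[1, 1] = f[2, 2] = True
        assert euler_characteristic(f, connectivity=8) == 1
        assert euler_characteristic(f, connectivity=4) == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_on_random_images(self, rng, connectivity):
        for _ in range(200):
            f = rng.random((16, 16)) > rng.uniform(0.3, 0.7)
            assert euler_characteristic(f, connectivity) == flood_fill_euler(f, connectivity)

    @settings(max_examples=60, deadline=None)
    @given(hnp.arrays(bool, (12, 12)))
    def test_matches_flood_fill_oracle_hypothesis(self, f):
        assert euler_characteristic(f, 8) == flood_fill_euler(f, 8)

    def test_agrees_with_skimage_reference(self, rng):
        from skimage.measure import euler_number

        for _ in range(50):
            f = rng.random((20, 20)) > 0.5
            assert euler_characteristic(f, 8) == euler_number(f, connectivity=2)
            assert euler_characteristic(f, 4) == euler_number(f, connectivity=1)


class TestP2OverA:
    def test_zero_perimeter(self):
        assert p2_over_a(0.0, 25.0) == 0.0

    def test_zero_area_convention(self):
        assert p2_over_a(10.0, 0.0) == 0.0

    @pytest.mark.parametrize("side", [2, 7, 31])
    def test_square_scale_invariance_is_16(self, side):
        sq = square_mask(side)
        assert p2_over_a(perimeter(sq, "boundary_edges"), area(sq)) == pytest.approx(16.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            p2_over_a(-1.0, 4.0)


class TestCurveAndIntegration:
    def test_two_level_image_constant_curve_and_sums(self, two_level_image):
        marking = two_level_image.pixels == 1.0
        curve = minkowski_curve(two_level_image, n_levels=80)
        a0 = area(marking)
        p0 = perimeter(marking, "crofton4")
        chi0 = euler_characteristic(marking)
        np.testing.assert_array_equal(curve.A, a0)
        np.testing.assert_allclose(curve.P, p0)
        np.testing.assert_array_equal(curve.chi, chi0)
        assert curve.sum_a == pytest.approx(80 * a0)
        assert curve.sum_euler == pytest.approx(80 * chi0)
        assert curve.sum_p2_over_a == pytest.approx(80 * p0**2 / a0)

    def test_constant_image_all_zero_curve(self):
        img = IntensityImage(pixels=np.full((10, 10), 0.0))
        curve = minkowski_curve(img)
        assert curve.sum_p == curve.sum_a == curve.sum_euler == curve.sum_p2_over_a == 0.0

    def test_integration_trivials(self):
        assert integrate_functional(np.ones(80)) == 80.0
        assert integrate_functional(np.zeros(80)) == 0.0
        assert integrate_functional([]) == 0.0

    def test_area_curve_monotone_non_increasing(self, rng):
        for _ in range(5):
            img = IntensityImage(pixels=rng.random((24, 24)))
            curve = minkowski_curve(img, n_levels=40)
            assert np.all(np.diff(curve.A) <= 0)

    def test_curve_dataframe_columns(self, two_level_image):
        df = minkowski_curve(two_level_image, n_levels=10).to_dataframe()
        assert list(df.columns) == ["level", "P", "A", "chi", "p2_over_a"]
        assert len(df) == 10


class TestAdditivityAndScaling:
    def test_measures_additive_over_separated_components(self, rng):
        a = np.zeros((30, 30), bool)
        a[3:9, 3:9] = True
        b = np.zeros((30, 30), bool)
        b[15:22, 14:25] = rng.random((7, 11)) > 0.4
        b[15, 14] = True
        both = a | b
        assert not (a & b).any()
        for fn in (area, lambda f: perimeter(f, "boundary_edges"), euler_characteristic):
            assert fn(both) == fn(a) + fn(b)

    @pytest.mark.parametrize("k", [2, 3])
    def test_integer_upscaling_behaviour(self, rng, k):
        f = rng.random((12, 12)) > 0.5
        big = np.kron(f, np.ones((k, k), bool))
        assert area(big) == k**2 * area(f)
        assert perimeter(big, "boundary_edges") == k * perimeter(f, "boundary_edges")
        assert euler_characteristic(big) == euler_characteristic(f)

    def test_thin_stroke_beats_disc_isoperimetrically(self):
        disc = digital_disc(10)  # area ~314
        stroke = np.zeros((40, 110), bool)
        stroke[19:22, 3:108] = True  # 3x105 = 315 px, same area
        assert abs(area(stroke) - area(disc)) < 0.05 * area(disc)
        for method in ("crofton4", "boundary_edges"):
            r_stroke = p2_over_a(perimeter(stroke, method), area(stroke))
            r_disc = p2_over_a(perimeter(disc, method), area(disc))
            assert r_stroke > r_disc
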