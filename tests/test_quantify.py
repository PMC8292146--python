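"""ROI geometry, densities, double positivity, distances, positive-pixel fraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtsaquant.detect import Detection
from mtsaquant.quantify import (
    RegionOfInterest,
    cell_density,
    double_positive,
    filter_to_roi,
    mean_shortest_distance,
    population_ratio,
    positive_pixel_fraction,
    subcapsular_band,
    subtract_population,
)
from mtsaquant.unmix import ChannelPlane, ConfigurationError


def dets(coords, marker="A"):
    return [Detection(float(x), float(y), 1.0, marker) for x, y in coords]


def rect_roi(w_px, h_px, pixel_size=1.0, capsule_top=True):
    poly = [(0, 0), (w_px, 0), (w_px, h_px), (0, h_px)]
    capsule = [(0, 0), (w_px, 0)] if capsule_top else None
    return RegionOfInterest([poly], capsule=capsule, pixel_size=pixel_size)


class TestRegionOfInterest:
    def test_area_in_mm2(self):
        # 2000 x 1000 px at 1 um/px = 2 mm2
        roi = rect_roi(2000, 1000, pixel_size=1.0)
        assert roi.area_mm2 == pytest.approx(2.0)

    def test_exclusions_reduce_area(self):
        roi = RegionOfInterest(
            [[(0, 0), (100, 0), (100, 100), (0, 100)]],
            exclusions=[[(10, 10), (30, 10), (30, 30), (10, 30)]],
            pixel_size=10.0,
        )
        assert roi.area_mm2 == pytest.approx((100 * 100 - 20 * 20) * 100 / 1e6)

    def test_self_intersecting_polygon_rejected(self):
        bowtie = [(0, 0), (10, 10), (10, 0), (0, 10)]
        with pytest.raises(ValueError):
            RegionOfInterest([bowtie])


class TestSubcapsularBand:
    def test_straight_capsule_band_area_matches_closed_form(self):
        # capsule along the top edge of a 3000 x 2000 um ROI at 1 um/px:
        # the 400 um band area is 400 x 3000 um2 (within 1%, allowing end caps)
        roi = rect_roi(3000, 2000, pixel_size=1.0)
        rest, band = subcapsular_band(roi, 400.0)
        assert band is not None
        expected = 400 * 3000 / 1e6
        assert band.area_mm2 == pytest.approx(expected, rel=0.01)
        assert rest.area_mm2 + band.area_mm2 == pytest.approx(roi.area_mm2, rel=1e-6)

    def test_zero_band_leaves_roi_unchanged(self):
        roi = rect_roi(100, 100)
        rest, band = subcapsular_band(roi, 0.0)
        assert band is None
        assert rest.area_mm2 == roi.area_mm2

    def test_remote_capsule_gives_empty_band(self):
        poly = [(0, 1000), (500, 1000), (500, 1500), (0, 1500)]
        roi = RegionOfInterest([poly], capsule=[(0, 0), (500, 0)], pixel_size=1.0)
        rest, band = subcapsular_band(roi, 400.0)
        assert band is None
        assert rest.area_mm2 == pytest.approx(roi.area_mm2)

    def test_missing_capsule_raises(self):
        roi = rect_roi(100, 100, capsule_top=False)
        with pytest.raises(ConfigurationError):
            subcapsular_band(roi, 400.0)

    def test_band_exclusion_never_increases_counts(self, rng):
        roi = rect_roi(1000, 1000, pixel_size=1.0)
        pts = dets(rng.uniform(0, 1000, size=(200, 2)))
        rest, _ = subcapsular_band(roi, 400.0)
        assert cell_density(pts, rest).count <= cell_density(pts, roi).count


def even_odd_inside(x, y, poly):
    """Classic even-odd ray-casting rule (independent point-in-polygon oracle)."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xi:
                inside = not inside
    return inside


class TestFilterToRoi:
    def test_centroid_of_convex_roi_retained(self):
        roi = rect_roi(100, 100)
        assert len(filter_to_roi(dets([(50, 50)]), roi)) == 1

    def test_point_in_exclusion_hole_removed(self):
        roi = RegionOfInterest(
            [[(0, 0), (100, 0), (100, 100), (0, 100)]],
            exclusions=[[(40, 40), (60, 40), (60, 60), (40, 60)]],
        )
        assert filter_to_roi(dets([(50, 50)]), roi) == []
        assert len(filter_to_roi(dets([(20, 20)]), roi)) == 1

    def test_boundary_point_counts_as_inside(self):
        roi = rect_roi(100, 100)
        assert len(filter_to_roi(dets([(0.0, 50.0)]), roi)) == 1

    def test_thousand_random_points_match_even_odd_oracle(self, rng):
        # non-convex inclusion polygon, no exclusions
        poly = [(0, 0), (100, 0), (100, 40), (50, 40), (50, 70), (100, 70), (100, 100), (0, 100)]
        roi = RegionOfInterest([poly])
        pts = rng.uniform(-10, 110, size=(1000, 2))
        got = {(p.x, p.y) for p in filter_to_roi(dets(pts), roi)}
        expected = {(x, y) for x, y in pts if even_odd_inside(x, y, poly)}
        assert got == expected


class TestCellDensity:
    def test_ten_points_in_one_mm2(self):
        roi = rect_roi(1000, 1000, pixel_size=1.0)
        q = cell_density(dets([(i * 50 + 10, 500) for i in range(10)]), roi, "CD3")
        assert q.density == pytest.approx(10.0)

    def test_empty_points_give_zero_density(self):
        q = cell_density([], rect_roi(1000, 1000, pixel_size=1.0), "CD3")
        assert q.count == 0 and q.density == 0.0

    def test_planted_density_recovered_from_ground_truth(self, small_scene):
        roi = small_scene.roi()
        gts = small_scene.detections("CD4")
        q = cell_density(gts, roi, "CD4")
        planted = len(gts) / roi.area_mm2
        assert q.density == pytest.approx(planted, rel=0.05)


class TestDoublePositivity:
    def test_coincident_detections_pair(self):
        a, b = dets([(10, 10)], "CD68"), dets([(10, 10)], "CD163")
        out = double_positive(a, b, 21.0, 1.0)
        assert len(out) == 1 and out[0].marker == "CD68+CD163+"

    def test_strict_threshold_excludes_radius_distance(self):
        # 5 um apart with a 4 um cut-off: not double-positive
        a, b = dets([(0, 0)]), dets([(5, 0)])
        assert double_positive(a, b, 4.0, 1.0) == []
        # strictness: exactly 4 um is also excluded
        assert double_positive(dets([(0, 0)]), dets([(4, 0)]), 4.0, 1.0) == []

    def test_planted_coloc_count_recovered_exactly(self):
        from mtsaquant.synthetic import generate_scene

        scene = generate_scene({"CD68": 40}, {("CD68", "CD163"): 0.5}, scene_size_um=800, seed=13)
        dp = double_positive(
            scene.detections("CD68"), scene.detections("CD163"), 21.0, scene.pixel_size
        )
        assert len(dp) == 20

    def test_one_b_cell_cannot_validate_two_a_cells(self):
        a = dets([(0, 0), (2, 0)])
        b = dets([(1, 0)], "B")
        assert len(double_positive(a, b, 4.0, 1.0)) == 1

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a_xy=st.lists(st.tuples(st.floats(0, 40), st.floats(0, 40)), max_size=10),
        b_xy=st.lists(st.tuples(st.floats(0, 40), st.floats(0, 40)), max_size=10),
        radius=st.floats(0.5, 25),
    )
    def test_partition_identity(self, a_xy, b_xy, radius):
        a, b = dets(a_xy), dets(b_xy, "B")
        dp = double_positive(a, b, radius, 1.0)
        rest = subtract_population(a, b, radius, 1.0)
        assert len(dp) + len(rest) == len(a)
        rest_xy = {(d.x, d.y) for d in rest}
        dp_xy = {(d.x, d.y) for d in dp}
        # the two outputs cover A (as coordinate sets) and are disjoint up to duplicates
        assert rest_xy | dp_xy == {(d.x, d.y) for d in a}

    def test_subtraction_trivial_cases(self):
        far_a, far_b = dets([(0, 0), (10, 10)]), dets([(1000, 1000)], "B")
        assert len(subtract_population(far_a, far_b, 4.0, 1.0)) == 2
        same = dets([(5, 5)])
        assert subtract_population(same, dets([(5, 5)], "B"), 4.0, 1.0) == []


class TestPopulationRatio:
    def quant(self, count, label="X"):
        from mtsaquant.quantify import PopulationQuant

        return PopulationQuant(label, count, 1.0, count / 1.0)

    def test_simple_ratio(self):
        assert population_ratio(self.quant(20), self.quant(10)) == 2.0

    def test_equal_counts(self):
        assert population_ratio(self.quant(7), self.quant(7)) == 1.0

    def test_zero_denominator_flagged_as_nan(self):
        assert math.isnan(population_ratio(self.quant(5), self.quant(0)))


class TestMeanShortestDistance:
    def test_source_subset_of_target_gives_zero(self):
        pts = dets([(1, 1), (5, 5)])
        s = mean_shortest_distance(pts, pts + dets([(9, 9)]), 0.49)
        assert s.mean_um == 0.0

    def test_single_pair_distance(self):
        s = mean_shortest_distance(dets([(0, 0)]), dets([(3, 4)]), 2.0)
        assert s.mean_px == pytest.approx(5.0)
        assert s.mean_um == pytest.approx(10.0)

    def test_empty_population_flagged_undefined(self):
        s = mean_shortest_distance([], dets([(0, 0)]), 1.0)
        assert not s.defined and math.isnan(s.mean_um)

    def test_matches_brute_force_oracle(self, rng):
        src = rng.uniform(0, 100, size=(50, 2))
        tgt = rng.uniform(0, 100, size=(50, 2))
        s = mean_shortest_distance(dets(src), dets(tgt), 1.0)
        brute = np.mean(
            [min(np.hypot(*(p - q)) for q in tgt) for p in src]
        )
        assert s.mean_um == pytest.approx(brute, abs=1e-9)


class TestPositivePixelFraction:
    def test_half_roi_positive_with_fixed_threshold(self):
        plane = np.zeros((100, 100))
        plane[:, 50:] = 1.0
        roi = rect_roi(100, 100)
        cp = ChannelPlane(plane, "F", "CD34")
        assert positive_pixel_fraction(cp, roi, "fixed", fixed_threshold=0.5) == pytest.approx(50.0, abs=1.5)

    def test_all_zero_plane_is_zero_percent(self):
        cp = ChannelPlane(np.zeros((50, 50)), "F", "CD34")
        assert positive_pixel_fraction(cp, rect_roi(50, 50), "fixed", fixed_threshold=0.1) == 0.0

    def test_planted_capillary_fraction_recovered(self):
        from mtsaquant.synthetic import generate_scene

        scene = generate_scene({}, scene_size_um=300, seed=21, capillary_fraction=0.10)
        cp = ChannelPlane(scene.capillary_mask.astype(np.float64), "F", "CD34",
                          pixel_size=scene.pixel_size)
        pct = positive_pixel_fraction(cp, scene.roi(), method="otsu")
        assert pct == pytest.approx(10.0, abs=1.0)

    def test_no_overlap_raises(self):
        cp = ChannelPlane(np.zeros((10, 10)), "F", "CD34")
        roi = RegionOfInterest([[(100, 100), (120, 100), (120, 120), (100, 120)]])
        with pytest.raises(ValueError):
            positive_pixel_fraction(cp, roi, "fixed", fixed_threshold=0.5)


class TestRigidInvariance:
    def test_density_invariant_under_rotation_and_translation(self, rng):
        pts = rng.uniform(100, 400, size=(60, 2))
        poly = np.array([(50, 50), (450, 50), (450, 450), (50, 450)], dtype=float)
        theta, shift = 0.6, np.array([37.0, -12.0])
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        roi_a = RegionOfInterest([list(map(tuple, poly))], pixel_size=1.0)
        roi_b = RegionOfInterest([list(map(tuple, poly @ R.T + shift))], pixel_size=1.0)
        qa = cell_density(dets(pts), roi_a)
        qb = cell_density(dets(pts @ R.T + shift), roi_b)
        assert qa.count == qb.count
        assert qa.density == pytest.approx(qb.density, rel=1e-9)
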