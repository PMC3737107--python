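"""Buffer geometry, nearest-feature distances and the randomization test."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from nestsurvey import (
    LandscapeLayer,
    SchemaError,
    mean_distance_summary,
    nearest_feature_distance,
    random_points_in_buffer,
    randomization_test,
    transect_buffer,
    unique_points,
)
from nestsurvey.spatial import habitat_feature_kruskal


def line_layer(kind="road", lines=None):
    lines = lines or [LineString([(0, 0), (0, 10000)])]
    return LandscapeLayer(kind, lines)


class TestNearestFeatureDistance:
    def test_point_on_feature_is_zero(self):
        layer = line_layer()
        d = nearest_feature_distance([[0.0, 5000.0]], layer, check_geographic=False)
        assert d[0] == 0.0

    def test_pythagorean_point_feature(self):
        layer = LandscapeLayer("settlement", [Point(0.0, 0.0)])
        d = nearest_feature_distance([[3.0, 4.0]], layer, check_geographic=False)
        assert d[0] == pytest.approx(5.0)

    def test_polyline_distance_matches_dense_sampling(self):
        rng = np.random.default_rng(5)
        verts = np.cumsum(rng.normal(0, 300, size=(8, 2)), axis=0) + 5000.0
        poly = LineString(verts)
        layer = LandscapeLayer("river", [poly])
        pt = np.array([[4000.0, 7000.0]])
        d = nearest_feature_distance(pt, layer, check_geographic=False)[0]
        # oracle: minimum over densely interpolated points of the polyline
        ts = np.linspace(0.0, poly.length, 10_000)
        samples = np.array([poly.interpolate(t).coords[0] for t in ts])
        oracle = np.sqrt(((samples - pt) ** 2).sum(axis=1)).min()
        assert d == pytest.approx(oracle, abs=0.1)

    def test_geographic_coordinates_rejected_by_default(self):
        layer = line_layer()
        with pytest.raises(SchemaError, match="geographic"):
            nearest_feature_distance([[3.0, 4.0]], layer)

    def test_unique_points_collapses_shared_gps_readings(self):
        pts = [[1000.0, 2000.0], [1000.0, 2000.0], [1500.0, 2500.0]]
        assert unique_points(pts).shape == (2, 2)


class TestTransectBuffer:
    def test_flat_caps_rectangle_area(self):
        # one straight 3 km transect, half-width 84 m: area = 2*0.084*3 km²
        line = LineString([(500_000, 1_200_000), (500_000, 1_203_000)])
        region = transect_buffer([line], 84.0)
        assert region.area_km2 == pytest.approx(0.504, rel=1e-6)

    def test_transect_points_inside_region(self):
        line = LineString([(500_000, 1_200_000), (500_000, 1_203_000)])
        region = transect_buffer([line], 84.0)
        assert region.region.contains(Point(500_000, 1_201_500))

    def test_overlapping_buffers_merge(self):
        l1 = LineString([(0, 0), (0, 3000)])
        l2 = LineString([(100, 0), (100, 3000)])  # 100 m apart, 84 m buffers overlap
        union = transect_buffer([l1, l2], 84.0)
        separate = 2 * transect_buffer([l1], 84.0).region.area
        assert union.region.area < separate
        # Monte-Carlo hit-or-miss oracle for the union area
        rng = np.random.default_rng(0)
        minx, miny, maxx, maxy = union.region.bounds
        n = 200_000
        xs = rng.uniform(minx, maxx, n)
        ys = rng.uniform(miny, maxy, n)
        import shapely

        frac = shapely.contains_xy(union.region, xs, ys).mean()
        mc_area = frac * (maxx - minx) * (maxy - miny)
        assert union.region.area == pytest.approx(mc_area, rel=0.01)

    def test_empty_or_degenerate_rejected(self):
        with pytest.raises(SchemaError):
            transect_buffer([], 84.0)
        with pytest.raises(SchemaError):
            transect_buffer([LineString([(0, 0), (0, 10)])], -1.0)


class TestRandomPoints:
    def test_containment_and_determinism(self):
        line = LineString([(500_000, 1_200_000), (500_000, 1_203_000)])
        region = transect_buffer([line], 84.0)
        pts = random_points_in_buffer(region, 214, seed=9)
        assert pts.shape == (214, 2)
        import shapely

        assert shapely.contains_xy(region.region, pts[:, 0], pts[:, 1]).all()
        again = random_points_in_buffer(region, 214, seed=9)
        np.testing.assert_array_equal(pts, again)

    def test_quadrant_uniformity(self):
        from scipy import stats

        line = LineString([(500_000, 1_200_000), (500_000, 1_204_000)])
        region = transect_buffer([line], 84.0)
        midy = 1_202_000
        n_ok = 0
        runs = 20
        for seed in range(runs):
            pts = random_points_in_buffer(region, 4000, seed=seed)
            q = (
                (pts[:, 0] >= 500_000).astype(int) * 2
                + (pts[:, 1] >= midy).astype(int)
            )
            counts = np.bincount(q, minlength=4)
            p = stats.chisquare(counts).pvalue
            n_ok += p > 0.01
        assert n_ok >= runs - 1


class TestRandomizationTest:
    @staticmethod
    def setup_geometry():
        line = LineString([(500_000, 1_200_000), (500_000, 1_203_000)])
        region = transect_buffer([line], 84.0)
        layer = LandscapeLayer("road", [LineString([(499_000, 1_199_000), (501_000, 1_199_000)])])
        return region, layer

    def test_single_rep_p_is_zero_or_one(self):
        region, layer = self.setup_geometry()
        nests = random_points_in_buffer(region, 20, seed=1)
        res = randomization_test(nests, layer, region, R=1, seed=2)
        assert res.p_one_sided in (0.0, 1.0)

    def test_seeded_determinism_bit_for_bit(self):
        region, layer = self.setup_geometry()
        nests = random_points_in_buffer(region, 30, seed=1)
        a = randomization_test(nests, layer, region, R=50, seed=7)
        b = randomization_test(nests, layer, region, R=50, seed=7)
        np.testing.assert_array_equal(a.null_means_m, b.null_means_m)
        assert (a.observed_mean_m, a.z, a.p_one_sided) == (
            b.observed_mean_m, b.z, b.p_one_sided,
        )

    def test_translation_invariance(self):
        region, layer = self.setup_geometry()
        nests = random_points_in_buffer(region, 25, seed=3)
        res = randomization_test(nests, layer, region, R=40, seed=11)
        shift = np.array([12_345.0, -6_789.0])
        line2 = LineString(np.asarray(region.transects[0].coords) + shift)
        region2 = transect_buffer([line2], region.half_width_m)
        layer2 = LandscapeLayer(
            "road", [LineString(np.asarray(layer.geometries[0].coords) + shift)]
        )
        res2 = randomization_test(nests + shift, layer2, region2, R=40, seed=11)
        assert res2.observed_mean_m == pytest.approx(res.observed_mean_m, abs=1e-6)
        np.testing.assert_allclose(res2.null_means_m, res.null_means_m, atol=1e-6)
        assert res2.z == pytest.approx(res.z, abs=1e-9)

    def test_moving_nests_farther_cannot_decrease_z(self):
        region, layer = self.setup_geometry()
        nests = random_points_in_buffer(region, 25, seed=5)
        res_near = randomization_test(nests, layer, region, R=60, seed=13)
        # push every nest north, strictly farther from the southern road
        farther = nests + np.array([0.0, 1500.0])
        res_far = randomization_test(farther, layer, region, R=60, seed=13)
        assert res_far.z >= res_near.z

    def test_null_calibration_smoke(self):
        # nests drawn from the null itself: one-sided p should look uniform
        region, layer = self.setup_geometry()
        rng = np.random.default_rng(100)
        pvals = []
        for i in range(40):
            nests = random_points_in_buffer(region, 40, seed=int(rng.integers(2**31)))
            res = randomization_test(
                nests, layer, region, R=99, seed=int(rng.integers(2**31)),
                collapse_duplicates=False,
            )
            pvals.append(res.p_one_sided)
        frac = np.mean(np.array(pvals) < 0.05)
        assert frac <= 0.20  # loose smoke bound; the tight one runs in acceptance


class TestSummaries:
    def test_constant_distances(self):
        mean, lo, hi = mean_distance_summary([2000.0, 2000.0])
        assert mean == 2.0 and lo == hi == 2.0

    def test_hand_computed_ci(self):
        d = np.array([1000.0, 2000.0, 3000.0])
        mean, lo, hi = mean_distance_summary(d)
        se = d.std(ddof=1) / np.sqrt(3)
        assert mean == pytest.approx(2.0)
        assert lo == pytest.approx((2000 - 1.96 * se) / 1000)
        assert hi == pytest.approx((2000 + 1.96 * se) / 1000)

    def test_kruskal_passthrough(self):
        rng = np.random.default_rng(0)
        d = np.concatenate([rng.normal(5000, 100, 30), rng.normal(1000, 100, 30)])
        labels = np.array(["DF"] * 30 + ["SAV"] * 30)
        res = habitat_feature_kruskal(d, labels)
        assert res.pvalue < 0.001
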