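"""The seven planning-accuracy metrics and their invariants."""

import numpy as np
import pytest
import shapely.affinity
from shapely.geometry import LineString, MultiPoint, Polygon

from neuroplan import metrics as m
from neuroplan import phantom as ph
from neuroplan import projection as proj
from neuroplan.errors import GeometryError, InvalidInputError
from neuroplan.projection import Quad2D

ELLIPSE_A, ELLIPSE_B = 31.2, 27.72


@pytest.fixture(scope="module")
def ellipse():
    return proj.ellipse_region(ELLIPSE_A, ELLIPSE_B, n=720)


def square_quad(half: float) -> Quad2D:
    return Quad2D(np.array([[half, -half], [half, half], [-half, half], [-half, -half]]))


def circle_quad_with_margins(circle, margins) -> Quad2D:
    """Axis-aligned quad around a centered circle with given edge margins."""
    r = 25.0
    o = [r + mm for mm in margins]  # +x, +y, -x, -y
    return Quad2D(np.array([[o[0], -o[3]], [o[0], o[1]], [-o[2], o[1]], [-o[2], -o[3]]]))


class TestCoverage:
    def test_identical_regions_full_coverage(self, ellipse):
        cov = m.coverage_metrics(ellipse, ellipse)
        assert cov.percent_coverage == pytest.approx(100.0)
        assert cov.excess == pytest.approx(0.0, abs=1e-9)

    def test_shifted_silhouette_reproduces_772_percent(self, ellipse):
        # 11.24 mm shift along the major axis -> lens overlap 77.2 %
        shifted = shapely.affinity.translate(ellipse, 11.24, 0.0)
        cov = m.coverage_metrics(shifted, ellipse)
        assert cov.percent_coverage == pytest.approx(77.2, abs=0.1)

    def test_shifted_plus_far_rectangle_reproduces_printed_excess(self, ellipse):
        # painted = shifted silhouette plus a disjoint 35.0 x 29.8 mm rectangle:
        # painted ~= 3,760 mm² and excess ~= 1,662 mm²
        shifted = shapely.affinity.translate(ellipse, 11.24, 0.0)
        rect = Polygon([(100, 0), (135.0, 0), (135.0, 29.8), (100, 29.8)])
        painted = shifted.union(rect)
        cov = m.coverage_metrics(painted, ellipse)
        assert cov.painted_area == pytest.approx(3760.0, abs=5.0)
        assert cov.excess == pytest.approx(1662.0, abs=5.0)

    def test_zero_area_silhouette_rejected(self, ellipse):
        with pytest.raises(GeometryError):
            m.coverage_metrics(ellipse, Polygon())

    def test_conservation_painted_equals_covered_plus_excess(self, ellipse, rng):
        for _ in range(200):
            pts = rng.uniform(-45, 45, (10, 2))
            painted = MultiPoint(pts).convex_hull
            if painted.geom_type != "Polygon" or painted.area == 0:
                continue
            cov = m.coverage_metrics(painted, ellipse)
            assert cov.painted_area == pytest.approx(cov.covered_area + cov.excess, rel=1e-12, abs=1e-9)
            assert 0.0 <= cov.percent_coverage <= 100.0
            assert cov.excess >= 0.0


class TestIncisionDeviation:
    def test_incision_through_epicenter_scores_zero(self, ellipse):
        assert m.incision_deviation(LineString([(-40, 0), (40, 0)]), ellipse) == pytest.approx(0.0, abs=1e-9)

    def test_tangent_incision_at_12mm(self, ellipse):
        assert m.incision_deviation(LineString([(-40, 12.0), (40, 12.0)]), ellipse) == pytest.approx(12.0)

    def test_matches_dense_sampling_oracle(self, ellipse, rng):
        c = proj.centroid(ellipse)
        for _ in range(20):
            seg = rng.uniform(-60, 60, (2, 2))
            ts = np.linspace(0, 1, 200001)[:, None]
            brute = np.min(np.linalg.norm(seg[0] + ts * (seg[1] - seg[0]) - c, axis=1))
            assert m.incision_deviation(LineString(seg), ellipse) == pytest.approx(brute, abs=1e-6)

    def test_empty_polyline_rejected(self, ellipse):
        with pytest.raises(InvalidInputError):
            m.incision_deviation([(1.0, 2.0)], ellipse)


class TestCraniotomyScore:
    def test_all_edges_at_10mm_scores_4(self, circle25):
        assert m.craniotomy_score(circle_quad_with_margins(circle25, [10] * 4), circle25) == 4

    def test_three_conforming_edges_score_3(self, circle25):
        quad = circle_quad_with_margins(circle25, [10, 10, 10, 25])
        assert m.craniotomy_score(quad, circle25) == 3

    def test_too_tight_craniotomy_scores_0(self, circle25):
        assert m.craniotomy_score(circle_quad_with_margins(circle25, [2] * 4), circle25) == 0

    def test_band_boundaries_inclusive(self, circle25):
        # margins exactly at the 5 and 15 mm band edges still score (closed band);
        # the iterative constructor realizes the asymmetric margins exactly
        quad = ph._craniotomy_for_margins(circle25, np.array([5.0, 15.0, 5.0, 15.0]))
        assert m.craniotomy_score(quad, circle25) == 4

    def test_score_monotone_as_margin_leaves_band(self, circle25):
        # moving one edge outward from the band: score never increases
        scores = [
            m.craniotomy_score(circle_quad_with_margins(circle25, [10, 10, 10, mm]), circle25)
            for mm in (10, 15, 18, 25, 40)
        ]
        assert all(s1 >= s2 for s1, s2 in zip(scores, scores[1:]))
        assert scores[0] == 4 and scores[-1] == 3


class TestUIncisionScore:
    @staticmethod
    def u_from_quad(quad: Quad2D) -> LineString:
        v = quad.vertices
        return LineString([v[0], v[1], v[2], v[3]])

    def test_congruent_all_10mm_scores_4(self, circle25):
        u = self.u_from_quad(circle_quad_with_margins(circle25, [10] * 4))
        assert m.u_incision_score(u, circle25) == 4

    def test_far_imaginary_base_scores_3(self, circle25):
        # limbs at 10 mm, base edge at 30 mm
        u = self.u_from_quad(circle_quad_with_margins(circle25, [10, 10, 10, 30]))
        assert m.u_incision_score(u, circle25) == 3

    def test_limbs_on_tumor_border_score_at_most_1(self, circle25):
        u = self.u_from_quad(circle_quad_with_margins(circle25, [0, 0, 0, 10]))
        assert m.u_incision_score(u, circle25) <= 1

    def test_wrong_limb_count_rejected(self, circle25):
        with pytest.raises(InvalidInputError):
            m.u_incision_score(LineString([(0, 0), (1, 0), (2, 0)]), circle25)


class TestMarginDeviationSum:
    def test_all_standard_margins_sum_zero(self, circle25):
        quad = circle_quad_with_margins(circle25, [10] * 4)
        assert m.margin_deviation_sum(quad, circle25) == pytest.approx(0.0, abs=1e-6)

    def test_all_edges_at_21_8mm_gives_47_2(self, circle25):
        quad = circle_quad_with_margins(circle25, [21.8] * 4)
        assert m.margin_deviation_sum(quad, circle25) == pytest.approx(47.2, abs=1e-3)

    def test_band_edge_margins_sum_20(self, circle25):
        quad = ph._craniotomy_for_margins(circle25, np.array([5.0, 15.0, 5.0, 15.0]))
        assert m.margin_deviation_sum(quad, circle25) == pytest.approx(20.0, abs=1e-3)

    def test_zero_sum_iff_perfect_score(self, circle25):
        quad = circle_quad_with_margins(circle25, [10] * 4)
        assert m.margin_deviation_sum(quad, circle25) == pytest.approx(0.0, abs=1e-6)
        assert m.craniotomy_score(quad, circle25) == 4

    def test_low_sum_does_not_imply_score_4(self, circle25):
        # sum = 18 mm but one edge far outside the band: score 3
        quad = ph._craniotomy_for_margins(circle25, np.array([10.0, 10.0, 10.0, 28.0]))
        assert m.margin_deviation_sum(quad, circle25) == pytest.approx(18.0, abs=1e-3)
        assert m.craniotomy_score(quad, circle25) == 3


class TestAssess:
    def test_zero_error_annotation_full_tuple(self, model):
        ann = ph.simulate_annotation(model, ph.SkillProfile.zero_error(), "AA1", rng=0)
        res = m.assess(ann, model)
        row = res.as_row()
        assert row["percent_coverage_pct"] == pytest.approx(100.0, abs=1e-9)
        assert row["excess_mm2"] == pytest.approx(0.0, abs=1e-9)
        assert row["incision_deviation_mm"] == pytest.approx(0.0, abs=1e-9)
        assert row["u_score_points"] == 4
        assert row["craniotomy_score_points"] == 4
        assert row["margin_deviation_sum_mm"] == pytest.approx(0.0, abs=1e-6)

    def test_assess_deterministic(self, model):
        ann = ph.simulate_annotation(model, ph.calibrated_profiles("intern", "AA1"), "AA1", rng=3)
        r1, r2 = m.assess(ann, model), m.assess(ann, model)
        assert r1 == r2

    def test_metrics_invariant_under_rigid_motion(self, model):
        ann = ph.simulate_annotation(model, ph.calibrated_profiles("intern", "AA1"), "AA1", rng=8)
        sil = model.silhouette()
        res = m.assess(ann, sil)

        def rt(g):
            return shapely.affinity.translate(shapely.affinity.rotate(g, 37.0, origin=(0, 0)), 12.0, -6.0)

        def rt_points(pts):
            return np.array([np.asarray(p.coords[0]) for p in rt(MultiPoint(pts)).geoms])

        moved = m.AnnotationSet(
            painted=rt(ann.painted),
            linear_incision=rt(ann.linear_incision),
            u_incision=rt(ann.u_incision),
            burr_holes=rt_points(ann.burr_holes),
            craniotomy=Quad2D(rt_points(ann.craniotomy.vertices)),
            assessment="AA1",
        )
        res2 = m.assess(moved, rt(sil))
        assert res2.coverage.percent_coverage == pytest.approx(res.coverage.percent_coverage, abs=1e-6)
        assert res2.coverage.excess == pytest.approx(res.coverage.excess, abs=1e-6)
        assert res2.incision_deviation == pytest.approx(res.incision_deviation, abs=1e-6)
        assert res2.u_score == res.u_score
        assert res2.cran_score == res.cran_score
        assert res2.margin_deviation_sum == pytest.approx(res.margin_deviation_sum, abs=1e-6)
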