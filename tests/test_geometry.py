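"""Unit and property tests for the intersecting-circle fusiform geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusiform import (
    FusiformGeometry,
    FusiformSpec,
    InfeasibleRatioError,
    InvalidGeometryError,
    angle_relations,
    arc_length,
    arc_width_ratio_from_beta,
    circle_radius,
    design_curves,
    inner_angle_from_lw,
    invert_arc_width_ratio,
    length_from_inner_angle,
    outline_polyline,
    pushout_distance,
)

# Derived oracle for the 3:1 design: chord-sum over a fine discretisation of
# the circular arc (computed once, frozen). The analytic value is
# theta_rad * r with theta = 4*atan(1/3), r = 2.5.
ARC_3_1 = 3.2175055439664217
PUSHOUT_3_1 = 0.10875277198321087

positive_dims = st.floats(min_value=0.05, max_value=50.0, allow_nan=False)


def discretized_arc_length(spec: FusiformSpec, n_segments: int) -> float:
    """Independent oracle: chord sum over a uniform sampling of the upper arc."""
    r = (spec.length_l**2 + spec.width_w**2) / (4.0 * spec.width_w)
    theta = 4.0 * math.atan2(spec.width_w, spec.length_l)
    phi = np.linspace(-theta / 2.0, theta / 2.0, n_segments + 1)
    pts = np.column_stack([r * np.sin(phi), r * np.cos(phi)])
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


class TestInnerAngle:
    @pytest.mark.parametrize(
        "l, w, beta",
        [
            (1.0, 1.0, 90.0),  # full circle: arctan(1) doubled
            (3.0, 1.0, 36.86989764584402),  # tangent angle rounds to 74 deg
            (2.18, 1.0, 49.28332399911668),  # the cohort's mean length-width ratio
        ],
    )
    def test_known_values(self, l, w, beta):
        assert inner_angle_from_lw(FusiformSpec(l, w)) == pytest.approx(beta, abs=1e-9)

    def test_canonical_iff_l_ge_w(self):
        assert inner_angle_from_lw(FusiformSpec(2.0, 1.0)) < 90.0
        assert inner_angle_from_lw(FusiformSpec(1.0, 2.0)) > 90.0
        assert not FusiformSpec(1.0, 2.0).is_canonical

    @pytest.mark.parametrize("l, w", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0), (math.nan, 1.0)])
    def test_invalid_spec_rejected(self, l, w):
        with pytest.raises(InvalidGeometryError):
            FusiformSpec(l, w)


class TestAngleRelations:
    def test_doubling_matches_reported_precision(self):
        # cohort mean inner angle 50.366 deg -> tangent angle 100.732,
        # within one rounding unit of the printed 100.731
        alpha, theta = angle_relations(50.366)
        assert alpha == theta == pytest.approx(100.732, abs=1e-9)
        assert abs(alpha - 100.731) < 0.0015

    @pytest.mark.parametrize("beta, alpha", [(90.0, 180.0), (15.0, 30.0)])
    def test_doubling(self, beta, alpha):
        assert angle_relations(beta) == (alpha, alpha)

    @pytest.mark.parametrize("beta", [0.0, -5.0, 180.0, 181.0])
    def test_out_of_range(self, beta):
        with pytest.raises(InvalidGeometryError):
            angle_relations(beta)


class TestLengthFromInnerAngle:
    def test_ratio_7_6_at_tangent_angle_30(self):
        # tangent angle 30 deg -> inner angle 15 deg -> l/w = cot(7.5 deg)
        assert length_from_inner_angle(15.0, 1.0) == pytest.approx(7.595754112725151)
        assert round(length_from_inner_angle(15.0, 1.0), 1) == 7.6

    def test_circle_limit(self):
        assert length_from_inner_angle(90.0, 1.0) == pytest.approx(1.0)

    def test_round_trip_with_inner_angle(self):
        l = length_from_inner_angle(36.86989764584402, 2.0)
        assert l == pytest.approx(6.0, abs=1e-9)
        assert inner_angle_from_lw(FusiformSpec(l, 2.0)) == pytest.approx(36.86989764584402)

    @pytest.mark.parametrize("beta", [0.0, -1.0, 180.0])
    def test_invalid_angle(self, beta):
        with pytest.raises(InvalidGeometryError):
            length_from_inner_angle(beta, 1.0)


class TestRadiusArcPushout:
    def test_radius_3_1_is_five_half_widths(self):
        r = circle_radius(FusiformSpec(3.0, 1.0))
        assert r == pytest.approx(2.5)
        assert r / 0.5 == pytest.approx(5.0)

    @pytest.mark.parametrize(
        "l, w, r", [(1.0, 1.0, 0.5), (4.0, 1.0, 4.25), (2.0, 1.0, 1.25)]
    )
    def test_radius_chord_sagitta(self, l, w, r):
        assert circle_radius(FusiformSpec(l, w)) == pytest.approx(r)

    def test_arc_semicircle(self):
        assert arc_length(FusiformSpec(1.0, 1.0)) == pytest.approx(math.pi / 2.0)

    def test_arc_3_1_matches_discretisation_oracle(self):
        spec = FusiformSpec(3.0, 1.0)
        assert arc_length(spec) == pytest.approx(ARC_3_1, rel=1e-12)
        oracle = discretized_arc_length(spec, 200_000)
        assert arc_length(spec) == pytest.approx(oracle, rel=1e-9)

    def test_arc_tends_to_chord_as_width_vanishes(self):
        for w in (1e-3, 1e-6):
            assert arc_length(FusiformSpec(2.0, w)) == pytest.approx(2.0, abs=1e-4)
        assert pushout_distance(FusiformSpec(2.0, 1e-6)) == pytest.approx(0.0, abs=1e-9)

    def test_pushout_values(self):
        assert pushout_distance(FusiformSpec(1.0, 1.0)) == pytest.approx((math.pi / 2 - 1) / 2)
        assert pushout_distance(FusiformSpec(3.0, 1.0)) == pytest.approx(PUSHOUT_3_1, rel=1e-12)


class TestInversion:
    def test_boundary_is_circle(self):
        assert invert_arc_width_ratio(math.pi / 2.0) == 90.0

    @pytest.mark.parametrize("beta", [5.0, 20.0, 36.87, 50.0, 75.0, 89.9])
    def test_round_trip(self, beta):
        rho = arc_width_ratio_from_beta(beta)
        assert invert_arc_width_ratio(rho) == pytest.approx(beta, abs=1e-8)

    def test_consistency_with_3_1_design(self):
        assert invert_arc_width_ratio(ARC_3_1) == pytest.approx(36.86989764584402, abs=1e-6)

    @pytest.mark.parametrize("rho", [0.0, 1.0, math.pi / 2 - 1e-9, -3.0, math.inf])
    def test_infeasible_ratio(self, rho):
        with pytest.raises(InfeasibleRatioError):
            invert_arc_width_ratio(rho)


class TestDesignCurves:
    def test_boundary_row(self):
        row = design_curves([90.0]).iloc[0]
        assert row["arc_width_ratio"] == pytest.approx(math.pi / 2)
        assert row["length_width_ratio"] == pytest.approx(1.0)
        assert row["pushout_width_ratio"] == pytest.approx((math.pi / 2 - 1) / 2)

    def test_monotonicity_and_identity(self):
        t = design_curves(np.linspace(0.5, 90.0, 500))
        assert np.all(np.diff(t["arc_width_ratio"]) < 0)
        assert np.all(np.diff(t["length_width_ratio"]) < 0)
        assert np.all(np.diff(t["pushout_width_ratio"]) > 0)
        np.testing.assert_allclose(
            t["arc_width_ratio"] - t["length_width_ratio"],
            2.0 * t["pushout_width_ratio"],
            rtol=1e-12,
            atol=1e-14,
        )

    @pytest.mark.parametrize("grid", [[0.0, 10.0], [10.0, 95.0], [-5.0], []])
    def test_invalid_grid(self, grid):
        with pytest.raises(InvalidGeometryError):
            design_curves(grid)


class TestOutline:
    def test_landmarks_present(self):
        out = outline_polyline(FusiformSpec(2.0, 1.0), points_per_arc=3)
        pts = {tuple(np.round(p, 12)) for p in out.points}
        assert {(-1.0, 0.0), (1.0, 0.0), (0.0, 0.5), (0.0, -0.5)} <= pts
        assert out.landmarks["A"] == (-1.0, 0.0)
        assert out.landmarks["D"] == (0.0, 0.5)

    def test_perimeter_converges_to_twice_arc(self):
        spec = FusiformSpec(3.0, 1.0)
        out = outline_polyline(spec, points_per_arc=100_001)
        assert out.perimeter() == pytest.approx(2.0 * arc_length(spec), rel=1e-6)

    def test_mirror_symmetry(self):
        out = outline_polyline(FusiformSpec(2.5, 0.8), points_per_arc=41)
        pts = {tuple(np.round(p, 10)) for p in out.points}
        for x, y in out.points:
            assert (round(-x, 10), round(y, 10)) in pts
            assert (round(x, 10), round(-y, 10)) in pts

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidGeometryError):
            outline_polyline(FusiformSpec(2.0, 1.0), points_per_arc=1)


class TestGeometryInvariants:
    """Property tests over random valid specs."""

    @given(l=positive_dims, w=positive_dims)
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_angle_identity_and_bounds(self, l, w):
        g = FusiformGeometry.from_lw(l, w)
        assert g.central_angle_theta == g.tangent_angle_alpha == pytest.approx(2 * g.inner_angle_beta)
        assert g.arc_a >= g.spec.length_l
        assert g.pushout_e == pytest.approx((g.arc_a - g.spec.length_l) / 2.0)
        assert g.pushout_e >= 0.0
        if g.spec.is_canonical:  # a/w >= pi/2 holds in the surgical regime l >= w
            assert g.ratio_a_w >= math.pi / 2.0 - 1e-12

    @given(l=positive_dims, w=positive_dims)
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_chord_sagitta_consistency(self, l, w):
        r = circle_radius(FusiformSpec(l, w))
        lhs = (l / 2.0) ** 2 + (r - w / 2.0) ** 2
        assert lhs == pytest.approx(r**2, rel=1e-12)

    @given(beta=st.floats(min_value=1.0, max_value=90.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_length_angle_round_trip(self, beta):
        l = length_from_inner_angle(beta, 1.0)
        assert inner_angle_from_lw(FusiformSpec(l, 1.0)) == pytest.approx(beta, abs=1e-9)

    def test_arc_width_ratio_minimum_at_circle(self):
        betas = np.linspace(1.0, 90.0, 200)
        ratios = [arc_width_ratio_from_beta(b) for b in betas]
        assert min(ratios) == ratios[-1] == pytest.approx(math.pi / 2.0)
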