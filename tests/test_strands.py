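"""Strand geometry (B-spline) and Hill constitutive laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oculoplant.anatomy import MuscleParams
from oculoplant.errors import InvariantError, ParameterError
from oculoplant.strands import (
    ElasticParams,
    Strand,
    arc_length,
    elastic_tension,
    evaluate_curve,
    force_length,
    force_velocity,
    muscle_tension,
    straight_strand,
)


def _deboor(control_points, knots, degree, s):
    """Independent naive de Boor recursion (the oracle)."""
    n = len(control_points)
    # find knot span k with knots[k] <= s < knots[k+1]
    if s >= knots[-1]:
        k = np.searchsorted(knots, knots[-1], side="left") - 1
        while knots[k] == knots[k + 1]:
            k -= 1
    else:
        k = int(np.searchsorted(knots, s, side="right")) - 1
    d = [np.array(control_points[j], dtype=float) for j in range(k - degree, k + 1)]
    for r in range(1, degree + 1):
        for j in range(degree, r - 1, -1):
            i = j + k - degree
            denom = knots[i + degree - r + 1] - knots[i]
            alpha = 0.0 if denom == 0.0 else (s - knots[i]) / denom
            d[j] = (1.0 - alpha) * d[j - 1] + alpha * d[j]
    return d[degree]


def _make_strand(pts):
    pts = np.asarray(pts, float)
    return Strand(
        control_points=pts,
        node_masses=np.full(len(pts), 0.1),
        strand_kind="elastic",
        params=ElasticParams(stiffness=50.0, rest_length=10.0),
        rest_length=10.0,
    )


def _params(**kw):
    base = dict(
        max_isometric_force=40.0,
        optimal_fiber_length=40.0,
        max_shortening_velocity=160.0,
        passive_slack_length=36.0,
        passive_stiffness_scale=2.0,
    )
    base.update(kw)
    return MuscleParams(**base)


class TestEvaluateCurve:
    def test_clamped_ends_return_end_control_points_exactly(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 3)) * 10
        s = _make_strand(pts)
        assert np.array_equal(evaluate_curve(s, 0.0), pts[0])
        assert np.array_equal(evaluate_curve(s, 1.0), pts[-1])

    def test_collinear_control_points_midpoint(self):
        pts = np.linspace([0, 0, 0], [9, 0, 0], 4)
        s = _make_strand(pts)
        np.testing.assert_allclose(evaluate_curve(s, 0.5), [4.5, 0, 0], atol=1e-12)

    def test_out_of_range_parameter_rejected(self):
        s = _make_strand(np.linspace([0, 0, 0], [9, 0, 0], 4))
        with pytest.raises(ParameterError):
            evaluate_curve(s, 1.2)
        with pytest.raises(ParameterError):
            evaluate_curve(s, -0.01)

    @pytest.mark.parametrize("n_ctrl", [4, 5, 8, 12])
    def test_matches_de_boor_oracle(self, n_ctrl):
        """Spline evaluation agrees with the naive de Boor recursion to
        1e-10 mm on random strands."""
        rng = np.random.default_rng(n_ctrl)
        for _ in range(30):
            pts = rng.normal(size=(n_ctrl, 3)) * 20
            strand = _make_strand(pts)
            knots = strand.spline.t
            for s in rng.uniform(0, 1, size=5):
                expected = _deboor(pts, knots, 3, float(s))
                np.testing.assert_allclose(
                    evaluate_curve(strand, float(s)), expected, atol=1e-10
                )

    def test_requires_four_control_points(self):
        with pytest.raises(InvariantError):
            _make_strand(np.zeros((3, 3)))


class TestArcLength:
    def test_straight_strand_length(self):
        s = _make_strand(np.linspace([0, 0, 0], [10, 0, 0], 6))
        assert arc_length(s) == pytest.approx(10.0, rel=1e-10)

    def test_circular_arc_analytic(self):
        """Control points on a circle: spline length approaches the analytic
        arc length as the control polygon refines (1e-3 relative here; the
        spline is an approximant, not an interpolant)."""
        radius, angle = 25.0, np.pi / 3
        t = np.linspace(0.0, angle, 24)
        pts = np.column_stack([radius * np.cos(t), radius * np.sin(t), np.zeros_like(t)])
        s = _make_strand(pts)
        assert arc_length(s) == pytest.approx(radius * angle, rel=1e-3)

    def test_arc_length_bounds_endpoint_distance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pts = rng.normal(size=(7, 3)) * 15
            s = _make_strand(pts)
            chord = np.linalg.norm(pts[-1] - pts[0])
            assert arc_length(s) >= chord - 1e-9


class TestForceLength:
    def test_normalized_at_optimum(self):
        assert force_length(1.0) == pytest.approx(1.0)

    def test_symmetric_about_optimum(self):
        w = 0.3
        assert force_length(1.0 + w, w) == pytest.approx(force_length(1.0 - w, w))

    def test_far_from_optimum_is_small(self):
        # Gaussian bell with w=0.3 at l_norm=0.4: exp(-4) ~= 0.0183
        val = force_length(0.4)
        assert val < 0.05
        assert val == pytest.approx(np.exp(-4.0), rel=1e-12)

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ParameterError):
            force_length(0.0)


class TestForceVelocity:
    def test_isometric_normalization(self):
        assert force_velocity(0.0) == pytest.approx(1.0)

    def test_zero_at_max_shortening(self):
        assert force_velocity(-1.0) == 0.0
        assert force_velocity(-1.5) == 0.0

    def test_hill_hyperbola_value_at_half_vmax(self):
        # (1 + v)/(1 - v/c) with c = 0.25 at v = -0.5: 0.5/3 = 1/6
        assert force_velocity(-0.5, curvature=0.25) == pytest.approx(1.0 / 6.0)

    def test_monotone_and_bounded_lengthening_plateau(self):
        v = np.linspace(-1.2, 5.0, 400)
        fv = force_velocity(v)
        assert np.all(np.diff(fv) >= -1e-12)
        assert fv.max() <= 1.8
        assert force_velocity(1e9) == pytest.approx(1.4, rel=1e-6)

    def test_c1_continuity_at_zero(self):
        eps = 1e-7
        left = (force_velocity(0.0) - force_velocity(-eps)) / eps
        right = (force_velocity(eps) - force_velocity(0.0)) / eps
        assert left == pytest.approx(right, rel=1e-4)


class TestMuscleTension:
    def test_inactive_at_slack_length_is_zero(self):
        p = _params()
        st_ = muscle_tension(p, 0.0, p.passive_slack_length, 0.0)
        assert st_.f_muscle == 0.0

    def test_max_isometric_definition(self):
        p = _params()
        st_ = muscle_tension(p, 1.0, p.optimal_fiber_length, 0.0)
        passive = muscle_tension(p, 0.0, p.optimal_fiber_length, 0.0).f_passive
        assert st_.f_muscle == pytest.approx(p.max_isometric_force + passive)

    def test_term_by_term_oracle(self):
        """F_active and F_passive recomputed independently term by term."""
        p = _params()
        a, l, v = 0.5, 1.1 * p.optimal_fiber_length, 0.0
        st_ = muscle_tension(p, a, l, v)
        fl = np.exp(-(((1.1 - 1.0) / p.fl_width) ** 2))
        expected_active = a * p.max_isometric_force * fl * 1.0
        strain = (l - p.passive_slack_length) / p.passive_slack_length
        expected_passive = p.passive_stiffness_scale * (
            np.exp(p.passive_toe_exponent * strain) - 1.0
        )
        assert st_.f_active == pytest.approx(expected_active, rel=1e-12)
        assert st_.f_passive == pytest.approx(expected_passive, rel=1e-12)
        assert st_.f_muscle == pytest.approx(expected_active + expected_passive, rel=1e-12)

    def test_activation_bounds_enforced(self):
        p = _params()
        with pytest.raises(ParameterError):
            muscle_tension(p, 1.2, 40.0)
        with pytest.raises(ParameterError):
            muscle_tension(p, -0.1, 40.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.0, 1.0),
        l_norm=st.floats(0.3, 1.8),
        v_norm=st.floats(-1.5, 1.5),
    )
    def test_decomposition_identity_and_nonnegativity(self, a, l_norm, v_norm):
        """F_muscle = F_active + F_passive holds to machine precision and all
        components are non-negative over the physiologic envelope."""
        p = _params()
        st_ = muscle_tension(
            p, a, l_norm * p.optimal_fiber_length, v_norm * p.max_shortening_velocity
        )
        assert st_.f_active >= 0.0
        assert st_.f_passive >= 0.0
        assert st_.f_muscle == st_.f_active + st_.f_passive

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        l_norm=st.floats(0.5, 1.5),
        v_norm=st.floats(-0.9, 0.9),
        a1=st.floats(0.0, 1.0),
        a2=st.floats(0.0, 1.0),
    )
    def test_monotone_in_activation(self, l_norm, v_norm, a1, a2):
        p = _params()
        lo, hi = sorted([a1, a2])
        f_lo = muscle_tension(p, lo, l_norm * p.optimal_fiber_length,
                              v_norm * p.max_shortening_velocity).f_muscle
        f_hi = muscle_tension(p, hi, l_norm * p.optimal_fiber_length,
                              v_norm * p.max_shortening_velocity).f_muscle
        assert f_hi >= f_lo - 1e-12


class TestElasticTension:
    def test_zero_at_rest_length(self):
        p = ElasticParams(stiffness=50.0, rest_length=8.0)
        assert elastic_tension(p, 8.0) == 0.0

    def test_linear_hooke_case(self):
        # exponent 1, strain 0.1, stiffness 50 gf -> 5 gf
        p = ElasticParams(stiffness=50.0, rest_length=10.0, exponent=1.0)
        assert elastic_tension(p, 11.0) == pytest.approx(5.0)

    def test_never_negative_under_compression(self):
        p = ElasticParams(stiffness=50.0, rest_length=10.0)
        assert elastic_tension(p, 5.0) == 0.0
        assert elastic_tension(p, 9.999999) == 0.0

    def test_continuous_at_rest_length(self):
        p = ElasticParams(stiffness=80.0, rest_length=10.0, exponent=1.5)
        assert elastic_tension(p, 10.0 + 1e-9) == pytest.approx(0.0, abs=1e-6)


def test_straight_strand_constructor_geometry():
    s = straight_strand([0, 0, 0], [12, 0, 0], 8, "elastic",
                        ElasticParams(10.0, 12.0), 12.0)
    assert len(s.control_points) == 8
    assert arc_length(s) == pytest.approx(12.0, rel=1e-9)
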