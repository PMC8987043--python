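"""Pulley-tube mechanics: contact, suspensions, OL coupling, pulley position."""

import numpy as np
import pytest

from oculoplant.errors import InvariantError
from oculoplant.pulley_tube import (
    ContactConstraint,
    PulleyTubeSpec,
    SuspensionSpec,
    contact_force,
    ol_insertion_coupling,
    pulley_position,
    suspension_forces,
    tube_frame,
    tube_point,
    validate_suspension_set,
)
from oculoplant.strands import ElasticParams


@pytest.fixture
def tube():
    return PulleyTubeSpec(
        center=np.array([10.0, 0.0, 0.0]),
        axis=np.array([0.0, 0.0, 1.0]),
        outward=np.array([1.0, 0.0, 0.0]),
        inner_radius=2.5,
        tube_length=4.0,
        contact=ContactConstraint(penalty_stiffness=100.0),
    )


class TestContactForce:
    def test_point_on_axis_no_force(self, tube):
        f = contact_force(np.array([10.0, 0.0, 0.0]), tube)
        assert np.allclose(f, 0.0)

    def test_linear_penalty_hand_computed(self, tube):
        # 0.1 mm penetration at 100 gf/mm -> 10 gf toward the axis
        p = np.array([10.0 + 2.6, 0.0, 0.5])
        f = contact_force(p, tube)
        np.testing.assert_allclose(f, [-10.0, 0.0, 0.0], atol=1e-12)

    def test_beyond_axial_extent_no_force(self, tube):
        p = np.array([10.0 + 5.0, 0.0, 2.5])
        assert np.allclose(contact_force(p, tube), 0.0)

    def test_force_is_purely_radial(self, tube):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = tube.center + rng.normal(size=3) * 3
            f = contact_force(p, tube)
            assert abs(f @ tube_frame(tube)[:, 2]) < 1e-12

    def test_tube_translation_moves_contact(self, tube):
        p = np.array([10.0 + 2.6, 0.0, 0.0])
        assert np.linalg.norm(contact_force(p, tube)) > 0
        assert np.allclose(contact_force(p, tube, translation=[0.2, 0, 0]), 0.0)


def _outer(name, anchor, ins, k=60.0, rest=None):
    rest = rest if rest is not None else float(np.linalg.norm(anchor))
    return SuspensionSpec(
        name=name, kind="outer", origin=np.asarray(anchor, float),
        insertion=np.asarray(ins, float),
        elastic=ElasticParams(stiffness=k, rest_length=rest),
    )


class TestSuspensionForces:
    def test_all_slack_zero_wrench(self, tube):
        # anchors exactly at natural length -> zero tension, zero wrench
        specs = []
        for name, (sy, az) in {
            "anterior_superior": (1, 2), "posterior_superior": (1, -2),
            "anterior_inferior": (-1, 2), "posterior_inferior": (-1, -2),
        }.items():
            ins = np.array([0.0, sy * 2.5, az])
            anchor = tube_point(tube, np.zeros(3), ins) + np.array([0.0, sy * 6.0, 0.0])
            specs.append(_outer(name, anchor, ins, rest=6.0))
        t, f, m = suspension_forces(tube, np.zeros(3), specs)
        assert np.allclose(t, 0.0)
        assert np.allclose(f, 0.0)
        assert np.allclose(m, 0.0)

    def test_vertical_displacement_restoring_force_hand_computed(self, tube):
        """Tube displaced 1 mm superiorly with symmetric linear suspensions:
        net inferior force equals the stretched suspensions' Hooke force
        minus the slackened ones (here: slack -> 0)."""
        ins_up = np.array([0.0, 2.5, 0.0])
        ins_dn = np.array([0.0, -2.5, 0.0])
        a_up = tube_point(tube, np.zeros(3), ins_up) + np.array([0.0, 6.0, 0.0])
        a_dn = tube_point(tube, np.zeros(3), ins_dn) - np.array([0.0, 6.0, 0.0])
        specs = [
            _outer("anterior_superior", a_up, ins_up, k=60.0, rest=6.0),
            _outer("anterior_inferior", a_dn, ins_dn, k=60.0, rest=6.0),
        ]
        t, f, m = suspension_forces(tube, np.array([0.0, 1.0, 0.0]), specs)
        # superior suspension now 5 mm (slack), inferior 7 mm: strain 1/6
        assert t[0] == 0.0
        assert t[1] == pytest.approx(60.0 / 6.0)
        np.testing.assert_allclose(f, [0.0, -10.0, 0.0], atol=1e-12)

    def test_mirror_symmetric_displacement_mirror_wrench(self, tube):
        specs = []
        for name, (sy, az) in {
            "anterior_superior": (1, 2), "posterior_superior": (1, -2),
            "anterior_inferior": (-1, 2), "posterior_inferior": (-1, -2),
        }.items():
            ins = np.array([0.0, sy * 2.5, az])
            anchor = tube_point(tube, np.zeros(3), ins) + np.array([0.5, sy * 6.0, 0.0])
            specs.append(_outer(name, anchor, ins, rest=5.0))
        _, f_up, m_up = suspension_forces(tube, np.array([0.0, 0.6, 0.0]), specs)
        _, f_dn, m_dn = suspension_forces(tube, np.array([0.0, -0.6, 0.0]), specs)
        # y-mirror: force flips y, moment flips x and z
        np.testing.assert_allclose(f_up * [1, -1, 1], f_dn, atol=1e-9)
        np.testing.assert_allclose(m_up * [-1, 1, -1], m_dn, atol=1e-9)


class TestOlInsertionCoupling:
    def test_zero_tension_zero_force(self):
        assert np.allclose(ol_insertion_coupling(0.0, [0, 0, -1]), 0.0)

    def test_direct_transmission(self):
        f = ol_insertion_coupling(10.0, np.array([0.0, 0.0, -2.0]))
        np.testing.assert_allclose(f, [0.0, 0.0, -10.0])


class TestPulleyPosition:
    def test_identity_pose_returns_configured_point(self, tube):
        local = np.array([2.5, 0.0, -2.0])
        expected = tube.center + tube_frame(tube) @ local
        np.testing.assert_allclose(pulley_position(tube, np.zeros(3), local), expected)

    def test_translation_shifts_position(self, tube):
        local = np.array([2.5, 0.0, -2.0])
        p0 = pulley_position(tube, np.zeros(3), local)
        p1 = pulley_position(tube, np.array([0.0, 1.0, 0.0]), local)
        np.testing.assert_allclose(p1 - p0, [0.0, 1.0, 0.0], atol=1e-12)

    def test_insertion_point_on_tube_radius_circle(self, tube):
        """A tube-frame insertion on the wall stays on the circle of its
        local radius for any azimuth of the insertion point."""
        r_local = 2.5
        for az in np.linspace(0, 2 * np.pi, 7):
            local = np.array([r_local * np.cos(az), r_local * np.sin(az), -2.0])
            p = pulley_position(tube, np.zeros(3), local)
            radial = p - tube.center
            radial -= (radial @ tube_frame(tube)[:, 2]) * tube_frame(tube)[:, 2]
            assert np.linalg.norm(radial) == pytest.approx(r_local, abs=1e-12)


class TestSuspensionSetValidation:
    def _full_set(self, tube):
        specs = []
        for name, (sy, az) in {
            "anterior_superior": (1, 2), "posterior_superior": (1, -2),
            "anterior_inferior": (-1, 2), "posterior_inferior": (-1, -2),
        }.items():
            ins = np.array([0.0, sy * 2.5, az])
            specs.append(_outer(name, tube.center + [0, sy * 8.0, az], ins))
        for name, local in {
            "inner_outward": [2.0, 0, 0], "inner_inward": [-2.0, 0, 0],
            "inner_superior": [0, 2.0, 0], "inner_inferior": [0, -2.0, 0],
        }.items():
            specs.append(
                SuspensionSpec(name=name, kind="inner", origin=0.0,
                               insertion=np.array(local, float),
                               elastic=ElasticParams(20.0, 1.5))
            )
        return specs

    def test_full_set_valid(self, tube):
        validate_suspension_set(self._full_set(tube))

    def test_seven_suspensions_rejected(self, tube):
        specs = self._full_set(tube)[:-1]
        with pytest.raises(InvariantError):
            validate_suspension_set(specs)

    def test_misnamed_outer_rejected(self, tube):
        specs = self._full_set(tube)
        specs[0].name = "superior"
        with pytest.raises(InvariantError):
            validate_suspension_set(specs)
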