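"""Plant dynamics: integration, force assembly, and static solving."""

import numpy as np
import pytest

from oculoplant.anatomy import make_default_anatomy
from oculoplant.errors import DivergenceError, ParameterError
from oculoplant.globe_dynamics import Plant, solve_static
from oculoplant.kinematics import fick_rotation, gaze_from_rotation

A0 = np.zeros(8)


class TestStep:
    def test_determinism_bit_identical(self, plant):
        s1 = plant.default_state()
        s2 = plant.default_state()
        A = np.full(8, 0.1)
        for _ in range(20):
            plant._step_inplace(s1, A, plant.config.sim.dt)
            plant._step_inplace(s2, A, plant.config.sim.dt)
        assert np.array_equal(s1.P, s2.P)
        assert np.array_equal(s1.q, s2.q)
        assert np.array_equal(s1.omega, s2.omega)

    def test_settled_state_is_near_fixed_point(self, plant):
        s = plant.default_state()
        before = s.P.copy()
        out = plant.step(s, A0, plant.config.sim.dt)
        # one step from the passively settled state barely moves anything
        # (residual creep < a few mm/s leaves sub-micrometre motion per step)
        assert np.max(np.abs(out.P - before)) < 2e-3

    def test_dt_ceiling_enforced(self, plant):
        s = plant.default_state()
        with pytest.raises(ParameterError):
            plant.step(s, A0, 2e-3)

    def test_quaternion_stays_unit_norm(self, plant):
        s = plant.default_state()
        A = np.array([0.5, 0.55, 0.0, 0.05, 0.0, 0.0, 0.0, 0.0])
        for _ in range(200):
            plant._step_inplace(s, A, plant.config.sim.dt)
        assert abs(np.linalg.norm(s.q) - 1.0) < 1e-9

    def test_instability_detector_raises(self, default_config):
        import copy

        cfg = copy.deepcopy(default_config)
        cfg.sim.instability_speed = 1e-6  # absurdly low detector threshold
        p = Plant(cfg)
        s = p.initial_state()
        with pytest.raises(DivergenceError):
            p.step(s, np.ones(8), cfg.sim.dt)

    def test_step_halving_convergence(self, plant):
        """Halving dt changes a 100 ms passive trajectory endpoint by a
        small amount (integration converges)."""
        sa = plant.default_state()
        sb = plant.default_state()
        A = np.array([0.3, 0.35, 0.0, 0.05, 0.0, 0.0, 0.0, 0.0])
        for _ in range(200):
            plant._step_inplace(sa, A, 5e-4)
        for _ in range(400):
            plant._step_inplace(sb, A, 2.5e-4)
        ga, gb = sa.gaze, sb.gaze
        # ~10 deg of rotation agrees within ~0.15 deg between step sizes
        assert abs(ga[0] - gb[0]) < 0.2
        assert abs(ga[1] - gb[1]) < 0.2


class TestForceAssembly:
    def test_internal_force_pairs_cancel(self, plant):
        """Newton's third law: every internal interaction is a +/- pair, so
        the assembled internal force total vanishes to machine precision."""
        s = plant.default_state()
        rng = np.random.default_rng(0)
        for _ in range(5):
            A = rng.uniform(0, 1, 8)
            rep = plant.assemble_generalized_forces(s, A)
            assert np.all(np.abs(rep.internal_sum) < 1e-9)

    def test_passive_equilibrium_small_torque(self, plant, central_solution):
        """At a converged central fixation the residual globe torque is
        small (the servo holds the eye against a near-zero imbalance)."""
        rep = plant.assemble_generalized_forces(
            central_solution.state, central_solution.A.values
        )
        assert np.linalg.norm(rep.globe_torque) < 5.0  # gf.mm

    def test_lr_activation_produces_abducting_velocity(self, plant):
        """Activating LR_GL alone at central gaze rotates the globe about
        the vertical (abducting) axis to within ~1 degree."""
        s = plant.default_state()
        act = np.zeros(8)
        act[0] = 0.5  # LR_GL
        dv = plant.predict_velocity(s, act) - plant.predict_velocity(s, A0)
        axis = dv / np.linalg.norm(dv)
        assert axis[1] > 0.999

    def test_activation_monotonically_increases_agonist_tension(self, plant):
        s = plant.default_state()
        sid = plant.muscle_readout["LR"]["GL"]
        prev = -1.0
        for a in (0.0, 0.25, 0.5, 0.75, 1.0):
            act = np.zeros(8)
            act[0] = a
            t = plant.assemble_generalized_forces(s, act).strand_tension[sid]
            assert t > prev
            prev = t

    def test_gl_confined_to_tube_bore(self, plant, central_solution):
        """The GL never strays outside the tube: radial excursion within the
        tube's axial extent stays below bore radius + tolerance."""
        s = central_solution.state
        for t_id, tube in enumerate(plant.tubes):
            pos = tube.spec.center + s.tube_pos[t_id]
            rel = s.P[tube.gl_nodes] - pos
            z = rel @ tube.R[:, 2]
            inside = np.abs(z) <= tube.spec.tube_length / 2
            radial = rel[inside] - np.outer(z[inside], tube.R[:, 2])
            rho = np.linalg.norm(radial, axis=1)
            assert np.all(
                rho <= tube.spec.inner_radius
                + tube.spec.contact.penetration_tolerance
            )


class TestPassiveRelaxation:
    def test_unique_equilibrium_from_random_perturbations(self, plant):
        """From random velocity kicks with zero innervation, kinetic energy
        dies out and the plant returns to one equilibrium: final gazes from
        10 perturbations agree within 0.1 deg."""
        rng = np.random.default_rng(0)
        finals = []
        for _ in range(10):
            s = plant.default_state()
            s.omega = rng.normal(0.0, 0.5, 3)
            s.V[plant.free] += rng.normal(0.0, 30.0, s.V[plant.free].shape)
            plant.settle(s, 1.5)
            assert np.linalg.norm(s.velocity_dps) < 1.0
            finals.append(s.gaze)
        finals = np.array(finals)
        spread = finals.max(axis=0) - finals.min(axis=0)
        assert np.all(spread < 0.1)


class TestSolveStatic:
    def test_central_fixation_contract(self, central_solution):
        A = central_solution.A.values
        assert np.all(A >= 0.0) and np.all(A <= 1.0)
        assert central_solution.info["gaze_error_deg"] < 0.05
        assert central_solution.info["speed_dps"] < 0.1

    def test_gaze_reached(self, central_solution):
        h, v = central_solution.state.gaze
        assert abs(h) < 0.05 and abs(v) < 0.05

    def test_out_of_range_target_rejected(self, default_config, plant):
        with pytest.raises(ParameterError):
            solve_static(default_config, (45.0, 0.0), plant=plant)

    def test_abduction_increases_lr_innervation(
        self, horizontal_sweep, central_solution
    ):
        """Fixation at 30 deg abduction recruits both LR layers above their
        central-gaze levels."""
        df = horizontal_sweep.records
        row30 = df[df["angle_deg"] == 30.0].iloc[0]
        assert row30["a_LR_GL"] > central_solution.A["LR_GL"]
        assert row30["a_LR_OL"] > central_solution.A["LR_OL"]

    def test_mirror_symmetric_plant_gives_swapped_solutions(self):
        """With vertical/oblique muscles symmetrized into the sagittal
        plane, fixations at +/-15 deg yield LR<->MR-swapped innervations."""
        cfg = make_default_anatomy()
        for name in ("SR", "IR", "SO", "IO"):
            m = cfg.muscles[name]
            m.origin = m.origin.copy()
            m.origin[0] = 0.0
            ins = m.insertion.copy()
            ins[0] = 0.0
            m.insertion = ins / np.linalg.norm(ins) * cfg.globe_radius
        p = Plant(cfg)
        sp = solve_static(cfg, (15.0, 0.0), plant=p)
        sm = solve_static(cfg, (-15.0, 0.0), plant=p)
        swapped = sm.A.values[[2, 3, 0, 1, 4, 5, 6, 7]]
        assert np.max(np.abs(sp.A.values - swapped)) < 1e-3


def test_gaze_round_trip_through_fick_rotation():
    for h, v in [(0, 0), (25, 0), (0, -18), (12, 7), (-30, 30)]:
        hh, vv = gaze_from_rotation(fick_rotation(h, v))
        assert hh == pytest.approx(h, abs=1e-9)
        assert vv == pytest.approx(v, abs=1e-9)
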