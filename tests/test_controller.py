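"""Neural controller: saccade phase, target profiles, and the innervation QP."""

import numpy as np
import pytest

from oculoplant.controller import (
    A_COMPONENTS,
    ControllerConfig,
    FixationTask,
    InnervationVector,
    SaccadeTask,
    classify_saccade_phase,
    make_target_velocity,
    minimum_jerk_fraction,
    minimum_jerk_speed,
    solve_innervation_qp,
)
from oculoplant.errors import ParameterError


class TestSaccadePhase:
    def test_rest_is_slow_phase(self):
        assert classify_saccade_phase(np.zeros(3)) is True

    def test_threshold_boundary(self):
        # "at least 20 deg/s" defines onset: 19.9 is still slow, 20.0 is not
        assert classify_saccade_phase([19.9, 0.0, 0.0]) is True
        assert classify_saccade_phase([20.0, 0.0, 0.0]) is False

    def test_mid_saccade_speed(self):
        assert classify_saccade_phase([400.0, 0.0, 0.0]) is False


class TestTargetVelocity:
    def test_fixation_zero_error_is_zero(self):
        v = make_target_velocity(FixationTask((10.0, 0.0)), t=0.3)
        assert np.allclose(v, 0.0)

    def test_minimum_jerk_peak_value(self):
        # closed form: peak speed = 1.875 * amplitude / duration at t = T/2
        amp, T = 30.0, 0.1
        assert minimum_jerk_speed(amp, T, T / 2) == pytest.approx(1.875 * amp / T)
        ts = np.linspace(0, T, 2001)
        speeds = [minimum_jerk_speed(amp, T, t) for t in ts]
        assert max(speeds) == pytest.approx(1.875 * amp / T, rel=1e-6)

    def test_profile_integrates_to_amplitude(self):
        amp, T = 30.0, 0.1
        ts = np.linspace(0, T, 20001)
        speeds = np.array([minimum_jerk_speed(amp, T, t) for t in ts])
        assert np.trapezoid(speeds, ts) == pytest.approx(amp, abs=1e-6)
        assert minimum_jerk_fraction(T, T) == 1.0

    def test_saccade_task_axis_and_amplitude(self):
        task = SaccadeTask((0.0, 0.0), (30.0, 0.0), duration=0.1)
        assert task.amplitude == pytest.approx(30.0, abs=1e-9)
        # pure abduction rotates about the +y (vertical) axis
        assert abs(task.axis[1]) > 0.999

    def test_invalid_duration_rejected(self):
        with pytest.raises(ParameterError):
            SaccadeTask((0, 0), (30, 0), duration=0.0)

    def test_servo_correction_clamped(self):
        v = make_target_velocity(
            FixationTask((0, 0)), 0.0,
            gaze_error_deg=np.array([0.0, 40.0, 0.0]), k_p=5.0, servo_limit=15.0,
        )
        assert np.linalg.norm(v) == pytest.approx(15.0)


def _grid_search_cost(v0, J, v_target, cfg, step=1e-3):
    """Dense lattice oracle over [0,1]^2 for a reduced 2-muscle plant."""
    a = np.arange(0.0, 1.0 + step / 2, step)
    A1, A2 = np.meshgrid(a, a, indexing="ij")
    # vectorised cost over the lattice
    r = (
        v0[:, None, None]
        + J[:, 0][:, None, None] * A1[None]
        + J[:, 1][:, None, None] * A2[None]
        - v_target[:, None, None]
    )
    cost = cfg.w_a * (A1**2 + A2**2) + cfg.w_x * np.sum(r**2, axis=0)
    i = np.unravel_index(np.argmin(cost), cost.shape)
    return float(cost[i]), np.array([A1[i], A2[i]])


class TestInnervationQP:
    def test_zero_target_at_equilibrium_gives_zero_innervation(self):
        # v0 = 0 (passive equilibrium), target 0: A = 0 is feasible + optimal
        cfg = ControllerConfig()
        J = np.array([[50.0, -40.0, 10.0, -5.0, 0.0, 0.0, 1.0, -1.0],
                      [5.0, 3.0, -6.0, 2.0, 30.0, -30.0, 2.0, -2.0],
                      [0.5, 0.2, -0.1, 0.3, 3.0, -3.0, 8.0, -8.0]])
        sol = solve_innervation_qp(np.zeros(3), J, np.zeros(3), cfg)
        assert np.all(sol.values < 1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_dense_grid_search_on_reduced_plant(self, seed):
        """On a 2-muscle antagonist toy plant, the QP solution's cost matches
        an exhaustive 0.001-step lattice search within 1e-5."""
        rng = np.random.default_rng(seed)
        cfg = ControllerConfig(w_a=1.0, w_x=1000.0)
        J = np.vstack([rng.uniform(20, 80) * np.array([1.0, -1.0])
                       + rng.normal(0, 2, 2),
                       rng.normal(0, 1, 2),
                       rng.normal(0, 0.5, 2)])
        v0 = rng.normal(0, 2, 3)
        v_target = rng.normal(0, 10, 3)
        sol = solve_innervation_qp(v0, J, v_target, cfg)
        ref_cost, ref_A = _grid_search_cost(v0, J, v_target, cfg)
        assert sol.cost <= ref_cost + 1e-5
        assert np.all(np.abs(sol.values - ref_A) <= 1e-3 + 1e-9)

    def test_differential_constraint_binding_exactly(self):
        """When the constraint binds, a_OL - a_GL equals the floor exactly
        after projection."""
        cfg = ControllerConfig()
        rng = np.random.default_rng(7)
        J = rng.normal(0, 30, (3, 8))
        J[:, 2] = np.abs(J[:, 2]) * 3  # make MR_GL attractive
        J[:, 3] = J[:, 3] * 0.01  # make MR_OL nearly useless
        v0 = np.zeros(3)
        v_target = J[:, 2] * 0.5  # wants a_MR_GL ~ 0.5
        sol = solve_innervation_qp(
            v0, J, v_target, cfg, diff_pairs=[(2, 3)],
        )
        A = sol.values
        assert A[2] > 0.05
        assert A[3] - A[2] >= cfg.differential_floor - 1e-9

    def test_feasibility_always_holds(self):
        cfg = ControllerConfig()
        rng = np.random.default_rng(11)
        for _ in range(20):
            J = rng.normal(0, rng.uniform(1, 100), (3, 8))
            v0 = rng.normal(0, 20, 3)
            vt = rng.normal(0, 50, 3)
            Ap = rng.uniform(0, 1, 8)
            sol = solve_innervation_qp(
                v0, J, vt, cfg, diff_pairs=[(0, 1), (2, 3)],
                A_prev=Ap, w_da=300.0, rate_limit=0.1,
            )
            A = sol.values
            assert np.all(A >= -1e-12) and np.all(A <= 1.0 + 1e-12)
            assert A[1] - A[0] >= cfg.differential_floor - 1e-9
            assert A[3] - A[2] >= cfg.differential_floor - 1e-9

    def test_parsimony_zeroing_an_active_component_raises_cost(self):
        """Local optimality: at the solution, zeroing any strictly positive
        component (keeping constraints satisfied) increases the cost."""
        cfg = ControllerConfig()
        rng = np.random.default_rng(3)
        J = rng.normal(0, 40, (3, 8))
        v0 = rng.normal(0, 5, 3)
        vt = rng.normal(0, 30, 3)
        sol = solve_innervation_qp(v0, J, vt, cfg)

        def cost(A):
            r = v0 + J @ A - vt
            return cfg.w_a * float(A @ A) + cfg.w_x * float(r @ r)

        base = cost(sol.values)
        for i in range(8):
            if sol.values[i] > 1e-6:
                trial = sol.values.copy()
                trial[i] = 0.0
                assert cost(trial) > base - 1e-9


def test_innervation_vector_named_access():
    v = InnervationVector(np.arange(8) / 10)
    assert v["MR_GL"] == pytest.approx(0.2)
    assert v.as_dict()["IO"] == pytest.approx(0.7)
    assert len(A_COMPONENTS) == 8
    with pytest.raises(ParameterError):
        InnervationVector(np.zeros(5))
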