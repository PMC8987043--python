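"""Inverse innervation by quadratic-cost optimal control in velocity space.

Every control step the controller solves for the 8-component innervation set

    A = [a_LR_GL, a_LR_OL, a_MR_GL, a_MR_OL, a_SR, a_IR, a_SO, a_IO]

by minimising

    w_a * ||A||^2  +  w_x * ||v_eye(A) - v_target||^2

over the box [0, 1]^8, where v_eye(A) is the globe angular velocity that
results from applying A over one control step (model-predictive, measured
by a trial rollout of the plant).  Around the currently applied innervation
the velocity response is locally affine in A, so each control step reduces
to a small convex QP; it is solved exactly (Cholesky + bounded-variable
least squares, enumerating the binding differential constraints) and the
result is projected onto the feasible set.

During fixation (and any phase with globe speed below the saccade threshold
of 20 deg/s) two linear constraints enforce greater orbital- than
global-layer innervation for each contracting horizontal rectus:
a_OL >= a_GL + 0.05.  A rectus counts as contracting when its solved GL
innervation exceeds a small threshold.  Between saccade onset and offset
(speed >= 20 deg/s) the constraints are lifted.  No reciprocal-innervation
pairing is assumed: the 8 actuators are independent.

Fixation targets use zero target velocity plus a small proportional
gaze-error servo (k_p * error); the pure zero-velocity target of the model
definition cannot correct position drift in a finite-stiffness plant, so the
servo term is explicit plumbing, documented in the methods note.  Saccade
targets follow a minimum-jerk velocity profile between the endpoint gazes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import ParameterError
from .kinematics import fick_rotation, rotation_error_deg

__all__ = [
    "A_COMPONENTS",
    "ControllerConfig",
    "ControllerSolution",
    "FixationTask",
    "InnervationVector",
    "SaccadeTask",
    "classify_saccade_phase",
    "linearize_velocity",
    "make_target_velocity",
    "minimum_jerk_speed",
    "solve_innervation",
    "solve_innervation_qp",
]

#: component order of the innervation vector A
A_COMPONENTS = ("LR_GL", "LR_OL", "MR_GL", "MR_OL", "SR", "IR", "SO", "IO")

#: (GL index, OL index) pairs eligible for the differential constraint
DIFFERENTIAL_PAIRS = {"LR": (0, 1), "MR": (2, 3)}


@dataclass
class InnervationVector:
    """The 8 unitless innervations, ordered as :data:`A_COMPONENTS`."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(A_COMPONENTS),):
            raise ParameterError(
                f"innervation vector must have {len(A_COMPONENTS)} components"
            )

    def __getitem__(self, key):
        if isinstance(key, str):
            return float(self.values[A_COMPONENTS.index(key)])
        return self.values[key]

    def as_dict(self) -> dict:
        return {name: float(v) for name, v in zip(A_COMPONENTS, self.values)}

    @classmethod
    def zeros(cls) -> "InnervationVector":
        return cls(np.zeros(len(A_COMPONENTS)))


@dataclass
class ControllerConfig:
    """Weights and thresholds of the neural controller.

    ``w_a`` weighs the summed squared innervation, ``w_x`` the squared
    velocity error in (deg/s)^2; velocity tracking dominates while the
    regulariser breaks actuator redundancy.  ``differential_floor`` is the
    enforced OL-over-GL innervation difference; ``saccade_velocity_threshold``
    (deg/s) defines saccade onset/offset; ``k_p`` (1/s) is the proportional
    fixation servo gain; ``control_interval`` (s) the controller period.
    """

    w_a: float = 1.0
    w_x: float = 1000.0
    differential_floor: float = 0.05
    saccade_velocity_threshold: float = 20.0
    k_p: float = 5.0
    control_interval: float = 0.005
    gl_active_threshold: float = 0.01
    solver_tol: float = 1e-12
    max_iter: float = 200
    #: innervation-rate regularisation w_da*||A - A_prev||^2 (numerical
    #: smoothing of the discrete-time loop; not part of the cost definition)
    w_da: float = 300.0
    #: finite-difference step for the local velocity linearisation
    fd_delta: float = 0.02
    #: ceiling (deg/s) on the proportional servo correction; large gaze
    #: errors are approached as a bounded slew instead of a saturating demand
    servo_velocity_limit: float = 15.0
    #: per-control-step trust region on |A - A_prev| during slow phases
    #: (numerical smoothing; saccadic phases use the larger saccade value so
    #: the agonist pulse can rise quickly)
    max_rate: float = 0.02
    max_rate_saccade: float = 0.5
    #: rate regularisation during saccadic phases (small, so the agonist can
    #: be released quickly instead of recruiting the antagonist as a brake)
    w_da_saccade: float = 2.0
    #: center (deg/s) and width of the smooth slow/saccadic blending of the
    #: rate regularisation and trust region
    phase_blend_speed: float = 16.0
    phase_blend_width: float = 3.0
    #: servo correction ceiling during saccade tasks (deg/s); the plant is
    #: allowed to finish a lagging saccade at saccadic speed
    servo_velocity_limit_saccade: float = 150.0

    def validate(self) -> "ControllerConfig":
        if self.w_a <= 0 or self.w_x <= 0:
            raise ParameterError("controller weights w_a, w_x must be > 0")
        if self.differential_floor < 0:
            raise ParameterError("differential_floor must be >= 0")
        return self

    @classmethod
    def field_names(cls):
        return tuple(cls.__dataclass_fields__)


@dataclass
class ControllerSolution:
    A: InnervationVector
    cost: float
    residual: float
    constraints_active: bool
    diff_pairs: Tuple[Tuple[int, int], ...] = ()


def classify_saccade_phase(v_eye, threshold: float = 20.0) -> bool:
    """True (constraints active) when globe speed is below the saccade
    threshold; saccade onset/offset is a speed of at least ``threshold``."""
    speed = float(np.linalg.norm(np.atleast_1d(np.asarray(v_eye, float))))
    return speed < threshold


# ---------------------------------------------------------------------------
# Target velocity generation
# ---------------------------------------------------------------------------

@dataclass
class FixationTask:
    gaze: Tuple[float, float]  # (horizontal, vertical) deg


@dataclass
class SaccadeTask:
    start: Tuple[float, float]
    end: Tuple[float, float]
    duration: float  # s
    profile: str = "minimum_jerk"

    def __post_init__(self):
        if self.duration <= 0:
            raise ParameterError(f"saccade duration must be > 0, got {self.duration}")
        R0 = fick_rotation(*self.start)
        R1 = fick_rotation(*self.end)
        rv = rotation_error_deg(R1, R0)  # degrees
        self.amplitude = float(np.linalg.norm(rv))
        self.axis = rv / self.amplitude if self.amplitude > 0 else np.zeros(3)


def minimum_jerk_speed(amplitude: float, duration: float, t: float) -> float:
    """Minimum-jerk speed profile (deg/s): peak 1.875*amplitude/duration at
    t = duration/2; integrates to ``amplitude`` over [0, duration]."""
    if t <= 0.0 or t >= duration:
        return 0.0
    tau = t / duration
    return amplitude / duration * 30.0 * (tau**2 - 2.0 * tau**3 + tau**4)


def minimum_jerk_fraction(duration: float, t: float) -> float:
    """Fraction of the displacement completed at time t (position profile)."""
    if t <= 0.0:
        return 0.0
    if t >= duration:
        return 1.0
    tau = t / duration
    return 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5


def target_rotation(task, t: float) -> np.ndarray:
    """Instantaneous target orientation matrix for a task at time t."""
    if isinstance(task, FixationTask):
        return fick_rotation(*task.gaze)
    frac = minimum_jerk_fraction(task.duration, t)
    h = task.start[0] + frac * (task.end[0] - task.start[0])
    v = task.start[1] + frac * (task.end[1] - task.start[1])
    return fick_rotation(h, v)


def make_target_velocity(
    task,
    t: float,
    gaze_error_deg: Optional[np.ndarray] = None,
    k_p: float = 5.0,
    servo_limit: float = 15.0,
) -> np.ndarray:
    """Target angular velocity (deg/s, 3-vector in the orbit frame).

    Fixation: zero target velocity, plus the proportional correction
    ``k_p * gaze_error_deg`` when the caller supplies the current orientation
    error (rotation vector, degrees); the correction magnitude is capped at
    ``servo_limit`` so distant targets are approached as a bounded slew.
    Saccade: minimum-jerk velocity along the rotation axis between the
    endpoint gazes, plus the same servo term relative to the moving target.
    """
    v = np.zeros(3)
    if isinstance(task, SaccadeTask):
        v = minimum_jerk_speed(task.amplitude, task.duration, t) * task.axis
    elif not isinstance(task, FixationTask):
        raise ParameterError(f"unknown task {task!r}")
    if gaze_error_deg is not None:
        corr = k_p * np.asarray(gaze_error_deg, float)
        mag = float(np.linalg.norm(corr))
        if mag > servo_limit:
            corr = corr * (servo_limit / mag)
        v = v + corr
    return v


# ---------------------------------------------------------------------------
# The Eq.-1 quadratic program
# ---------------------------------------------------------------------------

def linearize_velocity(
    plant,
    state,
    dt: float,
    A_base: Optional[np.ndarray] = None,
    delta: float = 0.1,
) -> Tuple[np.ndarray, np.ndarray]:
    """Local affine model v_eye(A) ~= v0 + J A (deg/s) from trial rollouts.

    The Jacobian is measured by finite differences of size ``delta`` around
    ``A_base`` (the innervation currently applied), which keeps the model
    accurate where the force-velocity nonlinearity matters; ``v0`` is the
    affine offset v(A_base) - J A_base.
    """
    n = len(A_COMPONENTS)
    A_base = np.zeros(n) if A_base is None else np.asarray(A_base, float)
    v_base = plant.predict_velocity(state, A_base, dt)
    J = np.empty((3, n))
    for i in range(n):
        d = delta if A_base[i] + delta <= 1.0 else -delta
        e = A_base.copy()
        e[i] += d
        J[:, i] = (plant.predict_velocity(state, e, dt) - v_base) / d
    return v_base - J @ A_base, J


def _project_feasible(
    A: np.ndarray, diff_pairs: Sequence[Tuple[int, int]], floor: float
) -> np.ndarray:
    """Exact feasibility projection: box bounds, then the active differential
    constraints."""
    A = np.clip(A, 0.0, 1.0)
    for gl, ol in diff_pairs:
        if A[ol] < A[gl] + floor:
            A[ol] = A[gl] + floor
            if A[ol] > 1.0:
                A[ol] = 1.0
                A[gl] = 1.0 - floor
    return A


def solve_innervation_qp(
    v0: np.ndarray,
    J: np.ndarray,
    v_target: np.ndarray,
    cfg: ControllerConfig,
    diff_pairs: Sequence[Tuple[int, int]] = (),
    x0: Optional[np.ndarray] = None,
    A_prev: Optional[np.ndarray] = None,
    w_da: float = 0.0,
    rate_limit: Optional[float] = None,
) -> "QPSolution":
    """Solve min_A w_a||A||^2 + w_x||v0 + J A - v_target||^2 over [0,1]^n
    subject to A[ol] - A[gl] >= floor for each pair.

    An optional rate regulariser w_da*||A - A_prev||^2 smooths the
    discrete-time loop, and an optional trust region ``rate_limit`` caps the
    per-call change |A - A_prev| (zero/None by default, i.e. the plain
    cost over the full box)."""
    n = J.shape[1]
    r0 = np.asarray(v0, float) - np.asarray(v_target, float)
    H = 2.0 * ((cfg.w_a + w_da) * np.eye(n) + cfg.w_x * (J.T @ J))
    g0 = 2.0 * cfg.w_x * (J.T @ r0)
    const = cfg.w_x * float(r0 @ r0)
    lo = np.zeros(n)
    hi = np.ones(n)
    if A_prev is not None:
        Ap = np.clip(np.asarray(A_prev, float), 0.0, 1.0)
        if w_da > 0.0:
            g0 = g0 - 2.0 * w_da * Ap
            const += w_da * float(Ap @ Ap)
        if rate_limit is not None:
            lo = np.maximum(lo, Ap - rate_limit)
            hi = np.minimum(hi, Ap + rate_limit)

    def cost(A):
        return 0.5 * A @ H @ A + g0 @ A + const

    def grad(A):
        return H @ A + g0

    A = _solve_qp_active_set(H, g0, diff_pairs, cfg.differential_floor, lo, hi)
    A = _project_feasible(A, diff_pairs, cfg.differential_floor)
    residual = _projected_gradient_norm(A, grad(A), diff_pairs, cfg.differential_floor)
    return QPSolution(A, float(cost(A)), residual, tuple(diff_pairs))


def _box_qp(H, g, lo, hi):
    """Exact min of 0.5 x'Hx + g'x over a box via bounded-variable least
    squares (H is positive definite; Cholesky turns the QP into a BVLS
    problem that scipy solves to optimality for these small sizes)."""
    from scipy.optimize import lsq_linear

    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    # bvls needs strictly increasing bounds; open up degenerate intervals
    hi = np.where(hi - lo < 1e-9, lo + 1e-9, hi)
    L = np.linalg.cholesky(H)
    C = L.T
    d = -np.linalg.solve(L, g)
    res = lsq_linear(C, d, bounds=(lo, hi), method="bvls", tol=1e-14)
    return np.clip(res.x, lo, hi)


def _solve_qp_active_set(H, g, diff_pairs, floor, lo, hi):
    """Exact solve of the box QP with optional differential constraints by
    enumerating the (at most 4) binding sets of the pair constraints; each
    candidate reduces to a bound-constrained QP solved exactly."""
    n = H.shape[0]
    diff_pairs = list(diff_pairs)
    best_x = None
    best_cost = np.inf

    def cost(x):
        return 0.5 * x @ H @ x + g @ x

    from itertools import chain, combinations

    for binding in chain.from_iterable(
        combinations(diff_pairs, r) for r in range(len(diff_pairs) + 1)
    ):
        free_pairs = [p for p in diff_pairs if p not in binding]
        if not binding:
            x = _box_qp(H, g, lo, hi)
        else:
            # substitute x[ol] = x[gl] + floor for each binding pair
            keep = [i for i in range(n) if i not in {ol for _, ol in binding}]
            E = np.zeros((n, len(keep)))
            f = np.zeros(n)
            col = {j: k for k, j in enumerate(keep)}
            for j in range(n):
                if j in col:
                    E[j, col[j]] = 1.0
            for gl, ol in binding:
                E[ol, col[gl]] = 1.0
                f[ol] = floor
            Hr = E.T @ H @ E
            gr = E.T @ (g + H @ f)
            lo_r = lo[keep].copy()
            hi_r = hi[keep].copy()
            feasible = True
            for gl, ol in binding:
                k = col[gl]
                lo_r[k] = max(lo_r[k], lo[ol] - floor)
                hi_r[k] = min(hi_r[k], hi[ol] - floor)
                if lo_r[k] > hi_r[k] + 1e-12:
                    feasible = False
            if not feasible:
                continue
            y = _box_qp(Hr, gr, lo_r, np.maximum(hi_r, lo_r))
            x = E @ y + f
        # feasibility of the non-substituted pair constraints
        if all(x[ol] >= x[gl] + floor - 1e-10 for gl, ol in free_pairs):
            c = cost(x)
            if c < best_cost:
                best_cost = c
                best_x = x
    if best_x is None:
        best_x = _box_qp(H, g, lo, hi)
    return best_x


@dataclass
class QPSolution:
    """Solution of one innervation QP (any number of actuators)."""

    values: np.ndarray
    cost: float
    residual: float
    diff_pairs: Tuple = ()


def _projected_gradient_norm(A, g, diff_pairs, floor: float = 0.05) -> float:
    """Norm of the gradient projected onto the feasible directions at A
    (KKT stationarity measure for the box; differential constraints checked
    by feasibility)."""
    pg = np.array(g, dtype=float)
    at_lo = A <= 1e-12
    at_hi = A >= 1.0 - 1e-12
    pg[at_lo & (pg > 0)] = 0.0
    pg[at_hi & (pg < 0)] = 0.0
    for gl, ol in diff_pairs:
        if abs(A[ol] - A[gl]) <= floor + 1e-9:
            # constraint near-active: remove the infeasible descent component
            d = pg[ol] - pg[gl]
            if d > 0:
                pg[ol] -= d / 2.0
                pg[gl] += d / 2.0
    return float(np.linalg.norm(pg))


def solve_innervation(
    plant,
    state,
    v_target: np.ndarray,
    cfg: ControllerConfig,
    constraints_active: bool,
    prev_A: Optional[np.ndarray] = None,
    linearization: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> ControllerSolution:
    """Solve the innervation QP for the full 8-muscle plant.

    When ``constraints_active`` (fixation / slow phases), the differential
    constraint a_OL >= a_GL + floor is applied to each horizontal rectus whose
    solved GL innervation exceeds ``cfg.gl_active_threshold``: a first pass is
    solved unconstrained to identify the contracting recti, then re-solved
    with the active pairs.
    """
    dt = getattr(plant, "trial_dt", None) or plant.config.sim.dt
    v0, J = (
        linearization
        if linearization is not None
        else linearize_velocity(plant, state, dt, prev_A, cfg.fd_delta)
    )
    # smooth blend between the slow-phase and saccadic regularisation so the
    # solution does not jump at the phase boundary; the commanded speed
    # participates so a saccade releases the previous innervation immediately
    speed = float(
        max(
            np.linalg.norm(np.asarray(state.velocity_dps)),
            np.linalg.norm(np.asarray(v_target, float)) / 3.0,
        )
    )
    f_slow = 1.0 / (1.0 + np.exp((speed - cfg.phase_blend_speed) / cfg.phase_blend_width))
    rate = cfg.max_rate_saccade + (cfg.max_rate - cfg.max_rate_saccade) * f_slow
    w_da = cfg.w_da_saccade + (cfg.w_da - cfg.w_da_saccade) * f_slow
    if not constraints_active:
        # between saccade onset and offset the controller has no innervation
        # memory at all: the previous solution is released immediately
        w_da = 0.0
    qp = solve_innervation_qp(
        v0, J, v_target, cfg, (), prev_A, A_prev=prev_A, w_da=w_da,
        rate_limit=rate,
    )
    pairs: Tuple[Tuple[int, int], ...] = ()
    if constraints_active:
        A = qp.values
        pairs = tuple(
            DIFFERENTIAL_PAIRS[m]
            for m in ("LR", "MR")
            if A[DIFFERENTIAL_PAIRS[m][0]] > cfg.gl_active_threshold
        )
        if pairs:
            qp = solve_innervation_qp(
                v0, J, v_target, cfg, pairs, A, A_prev=prev_A, w_da=w_da,
                rate_limit=rate,
            )
    return ControllerSolution(
        A=InnervationVector(qp.values),
        cost=qp.cost,
        residual=qp.residual,
        constraints_active=constraints_active,
        diff_pairs=pairs,
    )
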