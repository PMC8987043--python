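"""Scripted simulation experiments and their measurement operators.

The three canonical experiments of the model are

- *duction sweeps*: static fixations along the horizontal or vertical axis,
  recording innervations, layer/tendon tensions, suspension tensions and
  pulley positions per gaze;
- *sideslip measurement*: transverse displacement of a pulley (the OL
  insertion point on its tube) relative to a reference gaze, signed positive
  in the direction of the duction;
- *saccades*: open-loop minimum-jerk gaze transfers with the controller in
  the loop, recorded as time series of position, velocity, innervation and
  tension.

Results are pandas DataFrames wrapped with run metadata so they can be
written to CSV and reproduced from a manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import controller as ctrl
from .anatomy import OrbitConfig, config_hash
from .errors import ConvergenceError, ParameterError
from .globe_dynamics import ControlLoop, Plant, PlantState, solve_static
from .kinematics import fick_rotation, gaze_direction_error_deg, rotation_error_deg

__all__ = [
    "ExperimentResult",
    "run_duction_sweep",
    "run_fixation",
    "run_saccade",
    "measure_sideslip",
    "measure_inflection_angle",
    "tension_profile",
    "SUSPENSION_PAIRS",
]

#: superior/inferior suspension pairs (per tube) used by symmetry checks
SUSPENSION_PAIRS = (
    ("anterior_superior", "anterior_inferior"),
    ("posterior_superior", "posterior_inferior"),
    ("inner_superior_outward", "inner_inferior_outward"),
    ("inner_superior_inward", "inner_inferior_inward"),
)


@dataclass
class ExperimentResult:
    """Gaze- or time-indexed records of one experiment."""

    experiment_id: str
    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    states: Optional[Dict] = None  # per-record PlantState (not serialized)

    def __len__(self) -> int:
        return len(self.records)


def _record_row(plant: Plant, state: PlantState, A: np.ndarray) -> dict:
    r = plant.readout(state, A)
    row = {
        "gaze_h_deg": r["gaze_h_deg"],
        "gaze_v_deg": r["gaze_v_deg"],
        "speed_dps": r["speed_dps"],
    }
    for name, val in zip(ctrl.A_COMPONENTS, A):
        row[f"a_{name}"] = float(val)
    for m, v in r["insertional_tension"].items():
        row[f"tension_{m}_gf"] = v
    for layer in ("LR_GL", "LR_OL", "MR_GL", "MR_OL"):
        row[f"tension_{layer}_gf"] = r["tension"][layer]
    for name, v in r["suspension_tension"].items():
        row[f"suspension_{name.replace(':', '_')}_gf"] = v
    for tube, pos in r["pulley_position"].items():
        row[f"pulley_{tube}_x_mm"] = float(pos[0])
        row[f"pulley_{tube}_y_mm"] = float(pos[1])
        row[f"pulley_{tube}_z_mm"] = float(pos[2])
    return row


def run_fixation(
    config: OrbitConfig,
    gaze: Tuple[float, float],
    plant: Optional[Plant] = None,
):
    """Solve one static fixation and return (StaticSolution, record row)."""
    plant = plant or Plant(config)
    sol = solve_static(config, gaze, plant=plant)
    return sol, _record_row(plant, sol.state, sol.A.values)


def run_duction_sweep(
    config: OrbitConfig,
    axis: str,
    angles: Sequence[float],
    plant: Optional[Plant] = None,
    keep_states: bool = False,
) -> ExperimentResult:
    """Static fixation at each angle along one duction axis.

    Angles are solved center-outward with warm starts (the converged state of
    the nearest previously solved angle seeds the next), which keeps each
    solve short; records are returned sorted by angle.  A non-converged angle
    raises :class:`ConvergenceError` naming the failing angles.
    """
    if axis not in ("horizontal", "vertical"):
        raise ParameterError(f"axis must be horizontal|vertical, got {axis!r}")
    angles = list(angles)
    for a in angles:
        if abs(a) > 40:
            raise ParameterError(f"angle {a} outside +/-40 deg range")
    plant = plant or Plant(config)
    meta = {
        "experiment": f"{axis}_duction_sweep",
        "config_hash": config_hash(config),
        "angles": angles,
    }
    if not angles:
        return ExperimentResult(f"{axis}_duction_sweep", pd.DataFrame(), meta)

    order = sorted(range(len(angles)), key=lambda i: abs(angles[i]))
    rows: Dict[int, dict] = {}
    states: Dict[float, PlantState] = {}
    # warm-start bookkeeping: nearest solved angle seeds the next solve
    solved: List[Tuple[float, PlantState, np.ndarray]] = []
    failures = []
    for i in order:
        ang = angles[i]
        gaze = (ang, 0.0) if axis == "horizontal" else (0.0, ang)
        state0, prev_A = None, None
        if solved:
            nearest = min(solved, key=lambda t: abs(t[0] - ang))
            state0, prev_A = nearest[1], nearest[2]
        try:
            sol = solve_static(config, gaze, plant=plant, state0=state0, prev_A=prev_A)
        except ConvergenceError as exc:
            failures.append((ang, exc))
            continue
        solved.append((ang, sol.state, sol.A.values))
        row = _record_row(plant, sol.state, sol.A.values)
        row["angle_deg"] = ang
        row["converge_time_s"] = sol.info["time"]
        row["gaze_error_deg"] = sol.info["gaze_error_deg"]
        rows[i] = row
        if keep_states:
            states[ang] = sol.state
    if failures:
        raise ConvergenceError(
            f"{axis} sweep failed at angles {[a for a, _ in failures]}",
            residuals={str(a): e.residuals for a, e in failures},
        )
    df = pd.DataFrame([rows[i] for i in sorted(rows, key=lambda i: angles[i])])
    df = df.sort_values("angle_deg").reset_index(drop=True)
    return ExperimentResult(
        f"{axis}_duction_sweep", df, meta, states=states if keep_states else None
    )


def measure_sideslip(
    result: ExperimentResult,
    muscle: str,
    reference_angle: float = 0.0,
) -> pd.Series:
    """Signed transverse pulley sideslip (mm) per gaze, relative to the
    reference gaze.

    Transverse means perpendicular to the reference-gaze muscle path (whose
    direction is approximated by the tube axis, i.e. the straight muscle
    path), within the plane of the duction; the sign is positive in the
    direction of the duction (supraduction -> superior positive,
    abduction -> lateral positive).
    """
    if muscle not in ("LR", "MR"):
        raise ParameterError(f"pulley sideslip is defined for LR/MR, got {muscle!r}")
    df = result.records
    if "angle_deg" not in df.columns or not (df["angle_deg"] == reference_angle).any():
        raise ParameterError(f"reference angle {reference_angle} not in result")
    axis = "vertical" if "vertical" in result.experiment_id else "horizontal"
    cols = [f"pulley_{muscle}_{c}_mm" for c in "xyz"]
    pos = df[cols].to_numpy()
    ref = pos[np.argmax((df["angle_deg"] == reference_angle).to_numpy())]
    # duction direction in the orbit frame
    duction = np.array([0.0, 1.0, 0.0]) if axis == "vertical" else np.array([1.0, 0.0, 0.0])
    # path direction at reference ~ the straight-line course (dominantly +z);
    # transverse in-plane unit vector:
    path_dir = np.array([0.0, 0.0, 1.0])
    t_hat = duction - (duction @ path_dir) * path_dir
    t_hat = t_hat / np.linalg.norm(t_hat)
    slips = (pos - ref) @ t_hat
    return pd.Series(slips, index=df["angle_deg"].to_numpy(), name=f"{muscle}_sideslip_mm")


def measure_inflection_angle(
    plant: Plant,
    state: PlantState,
    muscle: str,
    duction_axis=(0.0, 1.0, 0.0),
) -> float:
    """Inflection (deg) of the muscle path at its pulley in the duction
    plane: the angle between the posterior path tangent (just behind the
    tube) and the anterior tangent (just in front), after projecting both
    into the plane spanned by the tube axis and the duction direction.

    The projection isolates the duction-plane bend from the muscle's fixed
    transverse course around the globe; for a vertical duction of a
    horizontal rectus the plane is sagittal (axis x duction = superior).
    """
    if muscle not in ("LR", "MR"):
        raise ParameterError(f"inflection is defined for LR/MR, got {muscle!r}")
    t_id = plant.muscle_readout[muscle]["tube"]
    tube = plant.tubes[t_id]
    pos = tube.spec.center + state.tube_pos[t_id]
    path = plant.muscle_path(state, muscle)
    z = (path - pos) @ tube.R[:, 2]
    half = tube.spec.tube_length / 2.0
    behind = np.where(z < -half)[0]
    ahead = np.where(z > half)[0]
    if len(behind) < 2 or len(ahead) < 2:
        raise ParameterError(f"path of {muscle} does not span the tube")
    d = np.asarray(duction_axis, float)
    normal = np.cross(tube.R[:, 2], d)
    normal = normal / np.linalg.norm(normal)

    def in_plane(v):
        v = v - (v @ normal) * normal
        return v / np.linalg.norm(v)

    post_tan = in_plane(path[behind[-1]] - path[behind[-2]])
    ant_tan = in_plane(path[ahead[1]] - path[ahead[0]])
    cosang = np.clip(post_tan @ ant_tan, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def run_saccade(
    config: OrbitConfig,
    from_gaze: Tuple[float, float],
    to_gaze: Tuple[float, float],
    duration: float,
    plant: Optional[Plant] = None,
    settle_time: float = 0.3,
    start_solution=None,
) -> ExperimentResult:
    """Simulate a saccade between two gazes with a minimum-jerk target
    profile, then hold fixation at the endpoint.

    Returns a time series at the control rate with positions, velocities,
    innervations, layer tensions and the saccade-phase flag.  The recorded
    endpoint gaze lies within 1 deg of the target.
    """
    for g in (from_gaze, to_gaze):
        if abs(g[0]) > 40 or abs(g[1]) > 40:
            raise ParameterError(f"gaze {g} outside +/-40 deg range")
    if duration <= 0:
        raise ParameterError(f"saccade duration must be > 0, got {duration}")
    plant = plant or Plant(config)
    start = start_solution or solve_static(config, from_gaze, plant=plant)
    state = start.state.copy()
    state.time = 0.0
    loop = ControlLoop(plant)
    loop.A = start.A.values.copy()
    task = ctrl.SaccadeTask(from_gaze, to_gaze, duration)
    cfg = config.controller
    total = duration + settle_time
    rows = []
    while state.time < total:
        R_t = ctrl.target_rotation(task, state.time)
        err = rotation_error_deg(R_t, state.rotation)
        v_t = ctrl.make_target_velocity(
            task, state.time, err, cfg.k_p, cfg.servo_velocity_limit_saccade
        )
        sol = loop.control(state, v_t)
        row = _record_row(plant, state, loop.A)
        row["time_s"] = state.time
        row["target_speed_dps"] = float(np.linalg.norm(v_t))
        row["constraints_active"] = bool(sol.constraints_active)
        row["velocity_h_dps"] = float(state.velocity_dps[1])
        row["velocity_v_dps"] = float(-state.velocity_dps[0])
        rows.append(row)
        loop.advance(state)
    final_err = np.linalg.norm(
        gaze_direction_error_deg(fick_rotation(*to_gaze), state.rotation)
    )
    df = pd.DataFrame(rows)
    meta = {
        "experiment": "saccade",
        "config_hash": config_hash(config),
        "from": tuple(from_gaze),
        "to": tuple(to_gaze),
        "duration_s": duration,
        "final_gaze_error_deg": float(final_err),
    }
    return ExperimentResult("saccade", df, meta, states={"final": state})


def tension_profile(result: ExperimentResult) -> pd.DataFrame:
    """Long-format (gaze, element, tension) table of a duction sweep."""
    df = result.records
    rows = []
    for _, rec in df.iterrows():
        gaze = (rec["gaze_h_deg"], rec["gaze_v_deg"])
        for col in df.columns:
            if col.startswith("tension_") and col.endswith("_gf"):
                rows.append(
                    {
                        "gaze_h_deg": gaze[0],
                        "gaze_v_deg": gaze[1],
                        "element": col[len("tension_"):-len("_gf")],
                        "kind": "muscle",
                        "tension_gf": rec[col],
                    }
                )
            elif col.startswith("suspension_") and col.endswith("_gf"):
                rows.append(
                    {
                        "gaze_h_deg": gaze[0],
                        "gaze_v_deg": gaze[1],
                        "element": col[len("suspension_"):-len("_gf")],
                        "kind": "suspension",
                        "tension_gf": rec[col],
                    }
                )
    return pd.DataFrame(rows)
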