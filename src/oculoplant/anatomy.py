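"""Orbit anatomy: parameter schema, validation, and the packaged defaults.

The model is a right eye in a right-handed orbit frame with the origin at the
globe center: +X lateral (abducting), +Y superior, +Z anterior.  Gaze is a
Fick angle pair (horizontal, vertical) in degrees; positive horizontal =
abduction, positive vertical = supraduction.

Six extraocular muscles act on the globe.  The horizontal recti (LR, MR) are
bilaminar: a global layer (GL) that passes through the pulley tube and, via
an elastic tendon, inserts on the sclera to rotate the eye, and an orbital
layer (OL) that inserts on the pulley tube itself and positions it.  The
vertical recti (SR, IR) and superior oblique (SO) are single contractile
strands in series with an elastic tendon; the inferior oblique (IO) is a
single contractile strand inserting directly.

Default numeric anatomy
-----------------------
The defaults are standard human values (globe radius 12 mm, rectus scleral
insertions near the spiral of Tillaux, origins ~36 mm posterior near the
annulus of Zinn, trochlea nasal-superior-anterior), packaged as an editable
configuration.  They are *consistent with* published anatomical measurements
but idealised: LR and MR are exactly mirror-symmetric about the sagittal
plane, and lengths derived from the geometry (optimal fibre lengths, slack
lengths, suspension rest lengths) are computed from the constructed paths
with explicit pretension factors.  Suspension stiffnesses and pretensions are
the product of the packaged calibration routine (see
:mod:`oculoplant.calibration`) and are frozen here.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from ._geometry import polyline_length as _polyline_length_pts, wrapped_path
from .controller import ControllerConfig
from .errors import InvariantError, ParameterError, ValidationError
from .pulley_tube import (
    INNER_SUSPENSION_NAMES,
    OUTER_SUSPENSION_NAMES,
    ContactConstraint,
    PulleyTubeSpec,
    SuspensionSpec,
    tube_frame,
    validate_suspension_set,
)
from .strands import ElasticParams

__all__ = [
    "MuscleParams",
    "SingleLayerMuscle",
    "BilaminarMuscle",
    "SimParams",
    "OrbitConfig",
    "MUSCLE_NAMES",
    "BILAMINAR_NAMES",
    "load_config",
    "write_config",
    "make_default_anatomy",
    "perturb_anatomy",
    "config_parameter_table",
    "config_hash",
]

SCHEMA_VERSION = 1

MUSCLE_NAMES = ("LR", "MR", "SR", "IR", "SO", "IO")
BILAMINAR_NAMES = ("LR", "MR")
SINGLE_NAMES = ("SR", "IR", "SO", "IO")

_ON_GLOBE_TOL = 1e-6


@dataclass
class MuscleParams:
    """Hill-model parameters of one contractile strand.

    Units: forces gf, lengths mm, velocities mm/s.  ``max_shortening_velocity``
    is the speed at which active force vanishes (FV(-1) = 0).  The passive
    element is an exponential toe above ``passive_slack_length`` scaled by
    ``passive_stiffness_scale`` with exponent ``passive_toe_exponent``, plus a
    linear viscosity ``passive_damping`` (gf.s/mm) representing passive tissue
    damping during fast length changes.
    """

    max_isometric_force: float
    optimal_fiber_length: float
    max_shortening_velocity: float
    passive_slack_length: float
    passive_stiffness_scale: float
    fl_width: float = 0.3
    fv_curvature: float = 0.25
    fv_lengthening_gain: float = 0.4
    passive_toe_exponent: float = 5.0
    passive_damping: float = 0.08

    def validate(self, where: str = "muscle") -> "MuscleParams":
        for name in (
            "max_isometric_force",
            "optimal_fiber_length",
            "max_shortening_velocity",
            "passive_slack_length",
            "passive_stiffness_scale",
            "fl_width",
            "fv_curvature",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvariantError(f"{where}.{name} must be strictly positive, got {v}")
        if self.passive_damping < 0 or self.fv_lengthening_gain < 0:
            raise InvariantError(f"{where}: damping and FV gain must be >= 0")
        return self


@dataclass
class SingleLayerMuscle:
    """A single-layer EOM: one contractile strand (optionally in series with
    an elastic tendon strand) from a fixed orbital origin to the sclera."""

    name: str
    origin: np.ndarray
    insertion: np.ndarray
    tendon_length: float
    params: MuscleParams
    tendon: Optional[ElasticParams] = None
    n_ctrl: int = 8
    tendon_n_ctrl: int = 4

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.insertion = np.asarray(self.insertion, dtype=float)


@dataclass
class BilaminarMuscle:
    """A horizontal rectus: GL + OL contractile strands, elastic tendon,
    pulley tube and its 8 suspensions."""

    name: str
    gl_origin: np.ndarray
    ol_origin: np.ndarray
    insertion: np.ndarray
    tendon_length: float
    gl_params: MuscleParams
    ol_params: MuscleParams
    tendon: ElasticParams
    tube: PulleyTubeSpec
    ol_tube_insertion: np.ndarray
    suspensions: List[SuspensionSpec] = field(default_factory=list)
    n_ctrl: int = 8
    tendon_n_ctrl: int = 4

    def __post_init__(self):
        self.gl_origin = np.asarray(self.gl_origin, dtype=float)
        self.ol_origin = np.asarray(self.ol_origin, dtype=float)
        self.insertion = np.asarray(self.insertion, dtype=float)
        self.ol_tube_insertion = np.asarray(self.ol_tube_insertion, dtype=float)


@dataclass
class SimParams:
    """Numerical parameters of the integrator (not physical anatomy)."""

    dt: float = 5e-4  # s, semi-implicit Euler step
    dt_max: float = 1e-3  # s, hard ceiling for step()
    node_mass: float = 0.1  # g per strand control node
    node_damping: float = 3000.0  # 1/s viscous rate on free nodes
    tube_mass: float = 0.5  # g
    tube_damping: float = 4000.0  # 1/s
    wrap_stiffness: float = 30.0  # gf/mm scleral-surface penalty
    wrap_clearance: float = 0.2  # mm strand clearance above the sclera
    reg_stiffness: float = 2.0  # gf node-spacing regularisation
    fv_time_constant: float = 0.008  # s first-order lag of the FV response
    inner_attach_halfwidth: float = 2.5  # mm axial kernel of the GL sliding attachment
    inner_damping: float = 0.02  # gf.s/mm GL-tube transverse damping
    gl_radius_proxy: float = 0.8  # mm effective GL strand radius
    instability_speed: float = 1e4  # mm/s divergence detector
    static_timeout: float = 10.0  # s simulated time before ConvergenceError
    velocity_tol: float = 0.1  # deg/s static convergence
    gaze_tol: float = 0.05  # deg static convergence
    settle_steps: int = 50  # consecutive in-tolerance steps required
    polish_time: float = 2.5  # s max extra servo time after criteria are met
    polish_tol: float = 0.002  # deg full-orientation error ending the polish
    polish_speed_tol: float = 0.05  # deg/s speed ending the polish


@dataclass
class OrbitConfig:
    """Complete, validated parameter set of the orbit model."""

    globe_radius: float
    globe_center: np.ndarray
    globe_mass: float
    orbital_stiffness: float  # gf.mm per deg of passive orbital-tissue torque
    orbital_damping: float  # gf.mm per (deg/s) of viscous orbital drag
    muscles: Dict[str, Union[SingleLayerMuscle, BilaminarMuscle]]
    #: additional passive stiffness (gf.mm/deg) about the line of sight;
    #: models the torsional stability the pulley apparatus and orbital
    #: tissues impose beyond the isotropic term
    orbital_torsion_stiffness: float = 20.0
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    sim: SimParams = field(default_factory=SimParams)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self):
        self.globe_center = np.asarray(self.globe_center, dtype=float)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "OrbitConfig":
        if self.globe_radius <= 0:
            raise InvariantError(f"globe_radius must be > 0, got {self.globe_radius}")
        if set(self.muscles) != set(MUSCLE_NAMES):
            raise ValidationError(
                f"muscles must be exactly {sorted(MUSCLE_NAMES)}, got {sorted(self.muscles)}"
            )
        bilaminar = [n for n, m in self.muscles.items() if isinstance(m, BilaminarMuscle)]
        if sorted(bilaminar) != sorted(BILAMINAR_NAMES):
            raise InvariantError(
                f"exactly LR and MR must be bilaminar, got {sorted(bilaminar)}"
            )
        for name, m in self.muscles.items():
            if m.tendon_length <= 0:
                raise InvariantError(f"muscles.{name}.tendon_length must be > 0")
            self._check_on_globe(name, m.insertion)
            if isinstance(m, BilaminarMuscle):
                m.gl_params.validate(f"muscles.{name}.gl_params")
                m.ol_params.validate(f"muscles.{name}.ol_params")
                m.tendon.validate()
                m.tube.validate(self.sim.gl_radius_proxy)
                try:
                    validate_suspension_set(m.suspensions)
                except InvariantError as exc:
                    raise InvariantError(f"muscles.{name}: {exc}") from exc
            else:
                m.params.validate(f"muscles.{name}.params")
                if m.tendon is not None:
                    m.tendon.validate()
        return self

    def _check_on_globe(self, name: str, point: np.ndarray) -> None:
        r = np.linalg.norm(np.asarray(point, float) - self.globe_center)
        if abs(r - self.globe_radius) > _ON_GLOBE_TOL:
            raise InvariantError(
                f"muscles.{name}.insertion is {abs(r - self.globe_radius):.3g} mm off "
                f"the globe surface (|p|={r:.6f}, radius={self.globe_radius})"
            )


# ---------------------------------------------------------------------------
# Serialization (structured-text YAML schema)
# ---------------------------------------------------------------------------

def _vec(x) -> list:
    return [float(v) for v in np.asarray(x, float).ravel()]


def _params_dict(p: MuscleParams) -> dict:
    return {k: float(v) for k, v in asdict(p).items()}


def _elastic_dict(e: Optional[ElasticParams]) -> Optional[dict]:
    if e is None:
        return None
    return {"stiffness": float(e.stiffness), "rest_length": float(e.rest_length),
            "exponent": float(e.exponent)}


def config_to_dict(config: OrbitConfig) -> dict:
    muscles = {}
    for name, m in config.muscles.items():
        if isinstance(m, BilaminarMuscle):
            muscles[name] = {
                "kind": "bilaminar",
                "gl_origin": _vec(m.gl_origin),
                "ol_origin": _vec(m.ol_origin),
                "insertion": _vec(m.insertion),
                "tendon_length": float(m.tendon_length),
                "gl_params": _params_dict(m.gl_params),
                "ol_params": _params_dict(m.ol_params),
                "tendon": _elastic_dict(m.tendon),
                "n_ctrl": int(m.n_ctrl),
                "tendon_n_ctrl": int(m.tendon_n_ctrl),
                "ol_tube_insertion": _vec(m.ol_tube_insertion),
                "tube": {
                    "center": _vec(m.tube.center),
                    "axis": _vec(m.tube.axis),
                    "outward": _vec(m.tube.outward),
                    "inner_radius": float(m.tube.inner_radius),
                    "tube_length": float(m.tube.tube_length),
                    "translate_dof": [bool(b) for b in m.tube.translate_dof],
                    "mesh_segments": int(m.tube.mesh_segments),
                    "contact": {
                        "penetration_tolerance": float(m.tube.contact.penetration_tolerance),
                        "penalty_stiffness": float(m.tube.contact.penalty_stiffness),
                    },
                },
                "suspensions": [
                    {
                        "name": s.name,
                        "kind": s.kind,
                        "origin": (_vec(s.origin) if s.kind == "outer" else float(s.origin)),
                        "insertion": _vec(s.insertion),
                        "elastic": _elastic_dict(s.elastic),
                    }
                    for s in m.suspensions
                ],
            }
        else:
            muscles[name] = {
                "kind": "single",
                "origin": _vec(m.origin),
                "insertion": _vec(m.insertion),
                "tendon_length": float(m.tendon_length),
                "params": _params_dict(m.params),
                "tendon": _elastic_dict(m.tendon),
                "n_ctrl": int(m.n_ctrl),
                "tendon_n_ctrl": int(m.tendon_n_ctrl),
            }
    return {
        "schema_version": int(config.schema_version),
        "globe_radius": float(config.globe_radius),
        "globe_center": _vec(config.globe_center),
        "globe_mass": float(config.globe_mass),
        "orbital_stiffness": float(config.orbital_stiffness),
        "orbital_damping": float(config.orbital_damping),
        "orbital_torsion_stiffness": float(config.orbital_torsion_stiffness),
        "muscles": muscles,
        "controller": {k: (float(v) if not isinstance(v, bool) else v)
                       for k, v in asdict(config.controller).items()},
        "sim": {k: (int(v) if k == "settle_steps" else float(v))
                for k, v in asdict(config.sim).items()},
    }


class _Reader:
    """Dict reader that raises ValidationError naming the offending field."""

    def __init__(self, data: dict, path: str = ""):
        if not isinstance(data, dict):
            raise ValidationError(f"{path or 'config'}: expected a mapping, got {type(data).__name__}")
        self.data = data
        self.path = path

    def _name(self, key: str) -> str:
        return f"{self.path}.{key}" if self.path else key

    def req(self, key: str):
        if key not in self.data:
            raise ValidationError(f"missing required field {self._name(key)!r}")
        return self.data[key]

    def opt(self, key: str, default=None):
        return self.data.get(key, default)

    def sub(self, key: str) -> "_Reader":
        return _Reader(self.req(key), self._name(key))

    def vec3(self, key: str) -> np.ndarray:
        v = self.req(key)
        arr = np.asarray(v, dtype=float)
        if arr.shape != (3,):
            raise ValidationError(f"{self._name(key)} must be a 3-vector, got {v!r}")
        return arr

    def num(self, key: str) -> float:
        v = self.req(key)
        try:
            return float(v)
        except (TypeError, ValueError):
            raise ValidationError(f"{self._name(key)} must be a number, got {v!r}")


def _params_from(r: _Reader) -> MuscleParams:
    return MuscleParams(
        max_isometric_force=r.num("max_isometric_force"),
        optimal_fiber_length=r.num("optimal_fiber_length"),
        max_shortening_velocity=r.num("max_shortening_velocity"),
        passive_slack_length=r.num("passive_slack_length"),
        passive_stiffness_scale=r.num("passive_stiffness_scale"),
        fl_width=r.num("fl_width"),
        fv_curvature=r.num("fv_curvature"),
        fv_lengthening_gain=r.num("fv_lengthening_gain"),
        passive_toe_exponent=r.num("passive_toe_exponent"),
        passive_damping=r.num("passive_damping"),
    )


def _elastic_from(r: _Reader) -> ElasticParams:
    return ElasticParams(
        stiffness=r.num("stiffness"),
        rest_length=r.num("rest_length"),
        exponent=r.num("exponent"),
    )


def config_from_dict(data: dict) -> OrbitConfig:
    root = _Reader(data)
    version = int(root.num("schema_version"))
    if version != SCHEMA_VERSION:
        raise ValidationError(
            f"schema_version {version} not supported (expected {SCHEMA_VERSION})"
        )
    muscles: Dict[str, Union[SingleLayerMuscle, BilaminarMuscle]] = {}
    mroot = root.req("muscles")
    if not isinstance(mroot, dict):
        raise ValidationError("muscles must be a mapping of muscle name -> record")
    for name, mdata in mroot.items():
        r = _Reader(mdata, f"muscles.{name}")
        kind = r.req("kind")
        if kind == "bilaminar":
            tr = r.sub("tube")
            cr = tr.sub("contact")
            tube = PulleyTubeSpec(
                center=tr.vec3("center"),
                axis=tr.vec3("axis"),
                outward=tr.vec3("outward"),
                inner_radius=tr.num("inner_radius"),
                tube_length=tr.num("tube_length"),
                translate_dof=tuple(bool(b) for b in tr.req("translate_dof")),
                mesh_segments=int(tr.num("mesh_segments")),
                contact=ContactConstraint(
                    penetration_tolerance=cr.num("penetration_tolerance"),
                    penalty_stiffness=cr.num("penalty_stiffness"),
                ),
            )
            suspensions = []
            for i, sdata in enumerate(r.req("suspensions")):
                sr = _Reader(sdata, f"muscles.{name}.suspensions[{i}]")
                skind = sr.req("kind")
                origin = sr.vec3("origin") if skind == "outer" else sr.num("origin")
                suspensions.append(
                    SuspensionSpec(
                        name=sr.req("name"),
                        kind=skind,
                        origin=origin,
                        insertion=sr.vec3("insertion"),
                        elastic=_elastic_from(sr.sub("elastic")),
                    )
                )
            muscles[name] = BilaminarMuscle(
                name=name,
                gl_origin=r.vec3("gl_origin"),
                ol_origin=r.vec3("ol_origin"),
                insertion=r.vec3("insertion"),
                tendon_length=r.num("tendon_length"),
                gl_params=_params_from(r.sub("gl_params")),
                ol_params=_params_from(r.sub("ol_params")),
                tendon=_elastic_from(r.sub("tendon")),
                tube=tube,
                ol_tube_insertion=r.vec3("ol_tube_insertion"),
                suspensions=suspensions,
                n_ctrl=int(r.num("n_ctrl")),
                tendon_n_ctrl=int(r.num("tendon_n_ctrl")),
            )
        elif kind == "single":
            tendon = r.opt("tendon")
            muscles[name] = SingleLayerMuscle(
                name=name,
                origin=r.vec3("origin"),
                insertion=r.vec3("insertion"),
                tendon_length=r.num("tendon_length"),
                params=_params_from(r.sub("params")),
                tendon=(_elastic_from(r.sub("tendon")) if tendon is not None else None),
                n_ctrl=int(r.num("n_ctrl")),
                tendon_n_ctrl=int(r.num("tendon_n_ctrl")),
            )
        else:
            raise ValidationError(f"muscles.{name}.kind must be bilaminar|single, got {kind!r}")
    ctrl_r = root.sub("controller")
    controller = ControllerConfig(**{k: ctrl_r.num(k) for k in ControllerConfig.field_names()})
    sim_r = root.sub("sim")
    sim_kwargs = {k: sim_r.num(k) for k in SimParams.__dataclass_fields__}
    sim_kwargs["settle_steps"] = int(sim_kwargs["settle_steps"])
    config = OrbitConfig(
        globe_radius=root.num("globe_radius"),
        globe_center=root.vec3("globe_center"),
        globe_mass=root.num("globe_mass"),
        orbital_stiffness=root.num("orbital_stiffness"),
        orbital_damping=root.num("orbital_damping"),
        orbital_torsion_stiffness=root.num("orbital_torsion_stiffness"),
        muscles=muscles,
        controller=controller,
        sim=SimParams(**sim_kwargs),
        schema_version=version,
    )
    return config.validate()


def write_config(config: OrbitConfig, path) -> None:
    """Serialize a config to the YAML schema (bit-exact round trip with
    :func:`load_config`)."""
    text = yaml.safe_dump(config_to_dict(config), sort_keys=True, default_flow_style=None)
    with open(path, "w") as fh:
        fh.write(text)


def load_config(path) -> OrbitConfig:
    """Load and fully validate an orbit configuration file."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValidationError(f"could not parse config {path}: {exc}") from exc
    return config_from_dict(data)


def config_hash(config: OrbitConfig) -> str:
    """Stable hash of the serialized configuration (for run manifests)."""
    import hashlib

    text = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def config_parameter_table(config: OrbitConfig) -> pd.DataFrame:
    """Flattened (parameter, value) table for documentation/CSV export."""
    rows = []

    def walk(prefix, obj):
        if isinstance(obj, dict):
            for k in sorted(obj):
                walk(f"{prefix}.{k}" if prefix else str(k), obj[k])
        elif isinstance(obj, (list, tuple)):
            for i, v in enumerate(obj):
                walk(f"{prefix}[{i}]", v)
        else:
            rows.append({"parameter": prefix, "value": obj})

    walk("", config_to_dict(config))
    return pd.DataFrame(rows, columns=["parameter", "value"])


# ---------------------------------------------------------------------------
# Default anatomy
# ---------------------------------------------------------------------------

def _mirror_x(v) -> np.ndarray:
    v = np.array(v, dtype=float)
    v[0] = -v[0]
    return v


def _unit(v) -> np.ndarray:
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


_polyline_length = _polyline_length_pts


# Calibration outcome of oculoplant.calibration.calibrate_suspensions on the
# packaged geometry: outer-suspension stiffness/pretension chosen so that
# vertical-duction pulley sideslip stays within physiologic bounds while the
# tube remains free to travel anteroposteriorly, and suspension tensions stay
# in the empirically reported band across horizontal gazes.
_OUTER_STIFFNESS = 50.0  # gf per unit strain
_OUTER_PRETENSION = {"anterior": 0.16, "posterior": 0.21}
_ANCHOR_LATERAL = 2.0  # mm outward offset of wall anchors from the tube
_ANCHOR_VERTICAL = 7.0  # mm superior/inferior offset
_ANCHOR_AXIAL = 2.5  # mm anterior/posterior offset
_INNER_STIFFNESS = 15.0
_INNER_PRETENSION = 0.50
_TENDON_STIFFNESS = 250.0
_GL_SLACK_FACTOR = 0.868
_GL_PASSIVE_SCALE = 2.3
_OL_SLACK_FACTOR = 0.93
_OL_PASSIVE_SCALE = 1.5
_RECTUS_SLACK_FACTOR = 0.88
_RECTUS_PASSIVE_SCALE = 2.0
_OBLIQUE_SLACK_FACTOR = 0.90
_OBLIQUE_PASSIVE_SCALE = 1.2


def _horizontal_rectus(side: int) -> BilaminarMuscle:
    """Build LR (side=+1) or MR (side=-1); exactly mirror-symmetric."""
    name = "LR" if side > 0 else "MR"
    globe_r = 12.0
    insertion = globe_r * np.array(
        [side * np.sin(np.deg2rad(55.0)), 0.0, np.cos(np.deg2rad(55.0))]
    )
    gl_origin = np.array([side * 6.0, 0.0, -36.0])
    ol_origin = np.array([side * 6.0, 0.0, -35.0])
    tube_center = np.array([side * 13.8, 0.0, -5.0])
    tube_axis = _unit(insertion - gl_origin)
    tube = PulleyTubeSpec(
        center=tube_center,
        axis=tube_axis,
        outward=np.array([float(side), 0.0, 0.0]),
        inner_radius=2.5,
        tube_length=4.0,
    )
    R = tube_frame(tube)
    z_t = R[:, 2]
    up = np.array([0.0, 1.0, 0.0])
    y_perp = _unit(up - (up @ z_t) * z_t)  # superior, perpendicular to the axis
    out_hint = np.array([float(side), 0.0, 0.0])
    out_perp = _unit(out_hint - (out_hint @ z_t) * z_t)  # away from the globe
    # tube-local attachment coordinates are derived from orbit-frame
    # intentions so LR and MR are exact mirror images despite the mirrored
    # tube frame handedness
    ol_tube_insertion = R.T @ (
        tube.inner_radius * out_perp - (tube.tube_length / 2.0) * z_t
    )

    suspensions: List[SuspensionSpec] = []
    lateral = np.array([float(side), 0.0, 0.0])
    for sus_name in OUTER_SUSPENSION_NAMES:
        sup = +1.0 if "superior" in sus_name else -1.0
        ant = +1.0 if "anterior" in sus_name else -1.0
        anchor = (
            tube_center
            + _ANCHOR_LATERAL * lateral
            + sup * _ANCHOR_VERTICAL * np.array([0.0, 1.0, 0.0])
            + np.array([0.0, 0.0, ant * _ANCHOR_AXIAL])
        )
        ins_local = R.T @ (
            sup * tube.inner_radius * y_perp + ant * (tube.tube_length / 2.0) * z_t
        )
        natural = float(np.linalg.norm(anchor - (tube_center + R @ ins_local)))
        pre = _OUTER_PRETENSION["anterior" if ant > 0 else "posterior"]
        suspensions.append(
            SuspensionSpec(
                name=sus_name,
                kind="outer",
                origin=anchor,
                insertion=ins_local,
                elastic=ElasticParams(
                    stiffness=_OUTER_STIFFNESS, rest_length=natural / (1.0 + pre)
                ),
            )
        )
    bore_r = 2.0
    s2 = np.sqrt(0.5)
    inner_locals = {
        "inner_superior_outward": R.T @ (bore_r * s2 * (out_perp + y_perp)),
        "inner_superior_inward": R.T @ (bore_r * s2 * (-out_perp + y_perp)),
        "inner_inferior_outward": R.T @ (bore_r * s2 * (out_perp - y_perp)),
        "inner_inferior_inward": R.T @ (bore_r * s2 * (-out_perp - y_perp)),
    }
    for sus_name in INNER_SUSPENSION_NAMES:
        suspensions.append(
            SuspensionSpec(
                name=sus_name,
                kind="inner",
                origin=0.0,
                insertion=inner_locals[sus_name],
                elastic=ElasticParams(
                    stiffness=_INNER_STIFFNESS,
                    rest_length=bore_r / (1.0 + _INNER_PRETENSION),
                ),
            )
        )

    # natural path lengths at the reference (central-gaze) construction
    tendon_length = 7.0
    tube_entry = tube_center + R @ np.array([0.0, 0.0, -tube.tube_length / 2.0])
    tube_exit = tube_center + R @ np.array([0.0, 0.0, tube.tube_length / 2.0])
    junction = insertion + tendon_length * _unit(tube_exit - insertion)
    gl_natural = _polyline_length([gl_origin, tube_entry, tube_exit, junction])
    ol_natural = _polyline_length(
        [ol_origin, tube_center + R @ ol_tube_insertion]
    )
    gl_params = MuscleParams(
        max_isometric_force=80.0,
        optimal_fiber_length=gl_natural,
        max_shortening_velocity=400.0,
        passive_slack_length=_GL_SLACK_FACTOR * gl_natural,
        passive_stiffness_scale=_GL_PASSIVE_SCALE,
        passive_damping=0.20,
    )
    ol_params = MuscleParams(
        max_isometric_force=20.0,
        optimal_fiber_length=ol_natural,
        max_shortening_velocity=160.0,
        passive_slack_length=_OL_SLACK_FACTOR * ol_natural,
        passive_stiffness_scale=_OL_PASSIVE_SCALE,
        passive_damping=0.05,
    )
    return BilaminarMuscle(
        name=name,
        gl_origin=gl_origin,
        ol_origin=ol_origin,
        insertion=insertion,
        tendon_length=tendon_length,
        gl_params=gl_params,
        ol_params=ol_params,
        tendon=ElasticParams(stiffness=_TENDON_STIFFNESS, rest_length=tendon_length),
        tube=tube,
        ol_tube_insertion=ol_tube_insertion,
        suspensions=suspensions,
    )


def _single_muscle(
    name: str,
    origin,
    insertion_dir,
    tendon_length: float,
    fmax: float,
    slack_factor: float,
    passive_scale: float,
    with_tendon: bool = True,
    vmax: float = 300.0,
) -> SingleLayerMuscle:
    globe_r = 12.0
    origin = np.asarray(origin, float)
    insertion = globe_r * _unit(insertion_dir)
    # natural path length measured over the sclera (obliques wrap the globe)
    path = _polyline_length(
        wrapped_path(origin, insertion, np.zeros(3), globe_r + 0.2)
    )
    muscle_natural = max(path - tendon_length, 5.0)
    params = MuscleParams(
        max_isometric_force=fmax,
        optimal_fiber_length=muscle_natural,
        max_shortening_velocity=vmax,
        passive_slack_length=slack_factor * muscle_natural,
        passive_stiffness_scale=passive_scale,
    )
    tendon = (
        ElasticParams(stiffness=_TENDON_STIFFNESS, rest_length=tendon_length)
        if with_tendon
        else None
    )
    return SingleLayerMuscle(
        name=name,
        origin=origin,
        insertion=insertion,
        tendon_length=tendon_length,
        params=params,
        tendon=tendon,
    )


def make_default_anatomy() -> OrbitConfig:
    """The packaged default human right-eye anatomy (deterministic).

    Defaults are consistent with cited human anatomy (globe radius 12 mm,
    spiral-of-Tillaux insertion distances, ~36 mm posterior origins), not
    transcribed from any single study; suspension stiffnesses carry the frozen
    calibration (see module docstring).
    """
    muscles: Dict[str, Union[SingleLayerMuscle, BilaminarMuscle]] = {
        "LR": _horizontal_rectus(+1),
        "MR": _horizontal_rectus(-1),
        "SR": _single_muscle(
            "SR", (-2.0, 4.0, -36.0), (0.0, np.sin(np.deg2rad(55.0)), np.cos(np.deg2rad(55.0))),
            6.0, 60.0, _RECTUS_SLACK_FACTOR, _RECTUS_PASSIVE_SCALE,
        ),
        "IR": _single_muscle(
            "IR", (-2.0, -4.0, -36.0), (0.0, -np.sin(np.deg2rad(55.0)), np.cos(np.deg2rad(55.0))),
            5.5, 60.0, _RECTUS_SLACK_FACTOR, _RECTUS_PASSIVE_SCALE,
        ),
        "SO": _single_muscle(
            "SO", (-13.0, 11.0, 5.0), (0.5, 0.72, -0.48),
            10.0, 20.0, _OBLIQUE_SLACK_FACTOR, _OBLIQUE_PASSIVE_SCALE,
            vmax=150.0,
        ),
        "IO": _single_muscle(
            "IO", (-11.0, -11.0, 6.0), (0.6, -0.55, -0.58),
            1.5, 20.0, _OBLIQUE_SLACK_FACTOR, _OBLIQUE_PASSIVE_SCALE,
            with_tendon=False, vmax=150.0,
        ),
    }
    config = OrbitConfig(
        globe_radius=12.0,
        globe_center=np.zeros(3),
        globe_mass=7.5,
        orbital_stiffness=10.0,
        orbital_damping=0.5,
        muscles=muscles,
    )
    return config.validate()


def perturb_anatomy(config: OrbitConfig, scale: float, seed: int) -> OrbitConfig:
    """Jitter attachment points by zero-mean Gaussian noise of the given
    relative scale (test-fixture generator; reseedable, deterministic).

    Scleral insertions are re-projected onto the globe so all invariants hold
    on the returned config.  scale must lie in [0, 0.2].
    """
    if not 0.0 <= scale <= 0.2:
        raise ParameterError(f"perturbation scale must lie in [0, 0.2], got {scale}")
    new = copy.deepcopy(config)
    if scale == 0.0:
        return new
    rng = np.random.default_rng(seed)

    def jitter(p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, float)
        sd = scale * max(np.linalg.norm(p), 1.0)
        return p + rng.normal(0.0, sd / 3.0, size=3)

    def reproject(p: np.ndarray) -> np.ndarray:
        rel = p - new.globe_center
        return new.globe_center + new.globe_radius * rel / np.linalg.norm(rel)

    for m in new.muscles.values():
        if isinstance(m, BilaminarMuscle):
            m.gl_origin = jitter(m.gl_origin)
            m.ol_origin = jitter(m.ol_origin)
            m.insertion = reproject(jitter(m.insertion))
            for s in m.suspensions:
                if s.kind == "outer":
                    s.origin = jitter(s.origin)
        else:
            m.origin = jitter(m.origin)
            m.insertion = reproject(jitter(m.insertion))
    return new.validate()
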