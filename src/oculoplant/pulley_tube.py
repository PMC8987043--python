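"""The pulley-tube system of a horizontal rectus muscle.

Each horizontal rectus pulley is a rigid tube (translation-free, rotation
locked) that acts as the common mechanical junction of three couplings:

- the orbital layer (OL) of the muscle inserts on the tube and positions it
  anteroposteriorly;
- four *outer* suspensions (non-contractile elastic strands) anchor the tube
  to the orbital wall at the anterior/posterior x superior/inferior corners;
- four *inner* suspensions couple the global layer (GL) running through the
  bore to the tube: they attach to the point where the GL crosses the tube
  mid-plane (a sliding attachment), restricting transverse GL motion while
  leaving longitudinal sliding free.

A frictionless penalty contact between the GL and the bore surface guarantees
the GL can never leave the tube even if the inner suspensions are overpowered.

The canonical "pulley position" reported by all sideslip metrics is the OL
insertion point on the tube, expressed in the orbit frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple, Union

import numpy as np

from .errors import InvariantError
from .strands import ElasticParams, elastic_tension

__all__ = [
    "ContactConstraint",
    "PulleyTubeSpec",
    "SuspensionSpec",
    "OUTER_SUSPENSION_NAMES",
    "contact_force",
    "ol_insertion_coupling",
    "pulley_position",
    "suspension_forces",
    "tube_frame",
    "tube_point",
]

#: canonical outer-suspension names (anterior/posterior x superior/inferior)
OUTER_SUSPENSION_NAMES = (
    "anterior_superior",
    "posterior_superior",
    "anterior_inferior",
    "posterior_inferior",
)

INNER_SUSPENSION_NAMES = (
    "inner_superior_outward",
    "inner_superior_inward",
    "inner_inferior_outward",
    "inner_inferior_inward",
)


@dataclass
class ContactConstraint:
    """Frictionless penalty contact between the GL and the tube bore."""

    penetration_tolerance: float = 0.05  # mm
    penalty_stiffness: float = 100.0  # gf/mm

    def validate(self) -> "ContactConstraint":
        if self.penetration_tolerance <= 0 or self.penalty_stiffness <= 0:
            raise InvariantError("contact tolerance and stiffness must be > 0")
        return self


@dataclass
class PulleyTubeSpec:
    """Rigid tube pose and dimensions.

    ``axis`` is the tube's longitudinal direction (unit, roughly along the
    muscle path, +z-ish = anterior); ``outward`` is a hint fixing the
    transverse frame (points away from the globe).  The tube may translate
    along the axes enabled in ``translate_dof``; rotation is locked.
    """

    center: np.ndarray
    axis: np.ndarray
    outward: np.ndarray
    inner_radius: float = 2.5
    tube_length: float = 4.0
    translate_dof: Tuple[bool, bool, bool] = (True, True, True)
    mesh_segments: int = 16
    contact: ContactConstraint = field(default_factory=ContactConstraint)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.outward = np.asarray(self.outward, dtype=float)

    def validate(self, gl_radius_proxy: float = 0.8) -> "PulleyTubeSpec":
        if self.tube_length <= 0:
            raise InvariantError("tube_length must be > 0")
        if self.inner_radius <= gl_radius_proxy:
            raise InvariantError(
                f"inner_radius {self.inner_radius} must exceed the GL strand "
                f"radius proxy {gl_radius_proxy} so the GL fits in the bore"
            )
        if not np.isfinite(self.center).all():
            raise InvariantError("tube center must be finite")
        if np.linalg.norm(self.axis) == 0:
            raise InvariantError("tube axis must be nonzero")
        self.contact.validate()
        return self


@dataclass
class SuspensionSpec:
    """One pulley suspension.

    outer: ``origin`` is the fixed anchor on the orbital wall (orbit frame,
    mm) and ``insertion`` the attachment point in the tube frame.
    inner: ``origin`` is the axial station (tube-frame z, mm) of the sliding
    attachment on the GL, and ``insertion`` the bore point in the tube frame.
    """

    name: str
    kind: str  # 'outer' | 'inner'
    origin: Union[np.ndarray, float]
    insertion: np.ndarray
    elastic: ElasticParams

    def __post_init__(self):
        if self.kind == "outer":
            self.origin = np.asarray(self.origin, dtype=float)
        else:
            self.origin = float(self.origin)
        self.insertion = np.asarray(self.insertion, dtype=float)

    def validate(self) -> "SuspensionSpec":
        if self.kind not in ("outer", "inner"):
            raise InvariantError(f"suspension kind must be outer|inner, got {self.kind!r}")
        self.elastic.validate()
        return self


def validate_suspension_set(specs: Sequence[SuspensionSpec]) -> None:
    """A horizontal rectus tube must carry exactly 4 outer + 4 inner
    suspensions, the outer ones named by their anterior/posterior x
    superior/inferior positions."""
    outer = [s for s in specs if s.kind == "outer"]
    inner = [s for s in specs if s.kind == "inner"]
    if len(outer) != 4 or len(inner) != 4:
        raise InvariantError(
            f"each tube needs exactly 4 outer + 4 inner suspensions, got "
            f"{len(outer)} outer + {len(inner)} inner"
        )
    names = sorted(s.name for s in outer)
    if names != sorted(OUTER_SUSPENSION_NAMES):
        raise InvariantError(
            f"outer suspensions must be named {OUTER_SUSPENSION_NAMES}, got {names}"
        )
    for s in specs:
        s.validate()


def tube_frame(spec: PulleyTubeSpec) -> np.ndarray:
    """Orthonormal tube frame as column matrix [x_out, y_up, z_axis]."""
    z = spec.axis / np.linalg.norm(spec.axis)
    x = spec.outward - np.dot(spec.outward, z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise InvariantError("tube outward hint is parallel to the axis")
    x = x / nx
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def tube_point(
    spec: PulleyTubeSpec, translation: np.ndarray, local_point: np.ndarray
) -> np.ndarray:
    """Orbit-frame position of a tube-frame point under the current pose."""
    R = tube_frame(spec)
    return spec.center + np.asarray(translation, float) + R @ np.asarray(local_point, float)


def pulley_position(
    spec: PulleyTubeSpec, translation: np.ndarray, ol_insertion_local: np.ndarray
) -> np.ndarray:
    """Canonical pulley position: the OL insertion point on the tube, in the
    orbit frame.  All sideslip metrics are defined on this point."""
    return tube_point(spec, translation, ol_insertion_local)


def contact_force(
    gl_point: np.ndarray, spec: PulleyTubeSpec, translation: np.ndarray = (0.0, 0.0, 0.0)
) -> np.ndarray:
    """Penalty contact force (gf) exerted by the tube bore on a GL point.

    Zero when the point lies within the bore radius or outside the tube's
    axial extent; otherwise a radially inward force proportional to the
    penetration.  The equal-and-opposite reaction acts on the tube.
    """
    R = tube_frame(spec)
    pos = spec.center + np.asarray(translation, float)
    rel = np.asarray(gl_point, float) - pos
    z = rel @ R[:, 2]
    if abs(z) > spec.tube_length / 2.0:
        return np.zeros(3)
    radial = rel - z * R[:, 2]
    rho = np.linalg.norm(radial)
    pen = rho - spec.inner_radius
    if pen <= 0.0 or rho < 1e-12:
        return np.zeros(3)
    return -spec.contact.penalty_stiffness * pen * (radial / rho)


def suspension_forces(
    spec: PulleyTubeSpec,
    translation: np.ndarray,
    specs: Sequence[SuspensionSpec],
    gl_attach_point: np.ndarray = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-suspension tensions and the resultant wrench on the tube.

    Outer suspensions run from their orbital-wall anchors to their tube-frame
    insertions; inner suspensions from their bore points to
    ``gl_attach_point`` (the sliding attachment where the GL crosses the tube
    mid-plane; required if any inner specs are present).

    Returns ``(tensions, force, moment)`` with the moment taken about the
    current tube center.
    """
    pos = spec.center + np.asarray(translation, float)
    tensions = np.zeros(len(specs))
    force = np.zeros(3)
    moment = np.zeros(3)
    for k, s in enumerate(specs):
        attach = tube_point(spec, translation, s.insertion)
        if s.kind == "outer":
            far = np.asarray(s.origin, float)
        else:
            if gl_attach_point is None:
                raise InvariantError("inner suspension requires a GL attachment point")
            far = np.asarray(gl_attach_point, float)
        d = far - attach
        length = np.linalg.norm(d)
        if length < 1e-12:
            continue
        t = elastic_tension(s.elastic, length)
        tensions[k] = t
        f = t * d / length
        force += f
        moment += np.cross(attach - pos, f)
    return tensions, force, moment


def ol_insertion_coupling(ol_tension: float, terminal_tangent: np.ndarray) -> np.ndarray:
    """Force (gf) transmitted to the tube by the OL at its insertion.

    ``terminal_tangent`` is the unit tangent of the OL at its tube insertion,
    pointing from the insertion back along the strand (the pull direction).
    The reaction acts on the OL's terminal node.
    """
    t = np.asarray(terminal_tangent, float)
    n = np.linalg.norm(t)
    if n < 1e-12 or ol_tension <= 0.0:
        return np.zeros(3)
    return float(ol_tension) * t / n
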