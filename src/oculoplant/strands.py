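"""Musculotendon strands: B-spline geometry and Hill-type constitutive laws.

A *strand* is the modelling primitive for a length of musculotendon (or a
pulley suspension): a clamped cubic B-spline curve whose control points carry
mass, together with a constitutive law giving the tension carried along the
curve.  Contractile-elastic strands use a three-element Hill model,

    F_muscle = F_active + F_passive
             = a . Fmax . FL(l/l_opt) . FV(v/v_max)  +  F_passive(l, v),

with activation a in [0, 1], strand length l (mm) and lengthening velocity v
(mm/s, positive = lengthening).  Purely elastic strands (tendons, pulley
suspensions) carry tension only above their rest length and can never push.

Constitutive curve shapes (the classic forms of the Hill literature; all
dimensionless, parameterised per muscle):

- FL: Gaussian bell ``exp(-((l_norm - 1)/w)^2)`` with width w (default 0.3);
  maximum 1 at the optimal fibre length.
- FV: Hill hyperbola ``(1 + v_norm)/(1 - v_norm/c)`` for shortening
  (v_norm in [-1, 0], curvature c = 0.25) and a saturating lengthening branch
  ``1 + g.v_norm/(v_norm + g/s)`` that is C1-continuous at v_norm = 0 and
  plateaus at 1 + g (default g = 0.4, i.e. plateau 1.4).
- passive: exponential toe ``k.(exp(c_toe.strain) - 1)`` above the slack
  length, zero below, plus a small linear viscosity ``c_v . v`` representing
  passive tissue damping; the total passive force is clamped at zero so a
  strand can never push.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.interpolate import BSpline

from .errors import InvariantError, ParameterError

__all__ = [
    "ElasticParams",
    "Strand",
    "StrandForceState",
    "arc_length",
    "elastic_tension",
    "evaluate_curve",
    "force_length",
    "force_velocity",
    "muscle_tension",
    "passive_force",
]

SPLINE_DEGREE = 3


@dataclass
class ElasticParams:
    """Constitutive parameters of a non-contractile elastic strand.

    ``stiffness`` is in gf per unit strain: tension = stiffness * strain^exponent
    for strain = (l - rest_length)/rest_length > 0, zero otherwise.
    """

    stiffness: float
    rest_length: float
    exponent: float = 1.0

    def validate(self) -> "ElasticParams":
        if self.stiffness < 0:
            raise InvariantError(f"elastic stiffness must be >= 0, got {self.stiffness}")
        if self.rest_length <= 0:
            raise InvariantError(f"elastic rest_length must be > 0, got {self.rest_length}")
        if self.exponent < 1:
            raise InvariantError(f"elastic exponent must be >= 1, got {self.exponent}")
        return self


@dataclass
class StrandForceState:
    """Decomposed tension of a contractile strand at one instant."""

    activation: float
    length: float
    velocity: float
    f_active: float
    f_passive: float
    f_muscle: float


@dataclass
class Strand:
    """A massed cubic B-spline musculotendon segment.

    ``control_points`` is an (n, 3) array, n >= 4.  ``params`` is a
    MuscleParams for contractile strands or :class:`ElasticParams` for elastic
    ones.  ``attachments`` records how each end is anchored (free text used by
    the plant builder: 'fixed', 'globe', 'tube', 'junction').
    """

    control_points: np.ndarray
    node_masses: np.ndarray
    strand_kind: Literal["contractile_elastic", "elastic"]
    params: object
    rest_length: float
    attachments: tuple = ("fixed", "fixed")
    _spline: Optional[BSpline] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=float)
        self.node_masses = np.asarray(self.node_masses, dtype=float)
        if self.control_points.ndim != 2 or self.control_points.shape[1] != 3:
            raise InvariantError("control_points must be an (n, 3) array")
        if len(self.control_points) < 4:
            raise InvariantError(
                f"a cubic strand needs >= 4 control points, got {len(self.control_points)}"
            )
        if len(self.node_masses) != len(self.control_points):
            raise InvariantError("node_masses must match control_points in length")
        if self.rest_length <= 0:
            raise InvariantError(f"rest_length must be > 0, got {self.rest_length}")
        if self.strand_kind not in ("contractile_elastic", "elastic"):
            raise InvariantError(f"unknown strand_kind {self.strand_kind!r}")

    @property
    def spline(self) -> BSpline:
        if self._spline is None:
            self._spline = _clamped_bspline(self.control_points)
        return self._spline


def _clamped_knots(n_ctrl: int, degree: int = SPLINE_DEGREE) -> np.ndarray:
    """Clamped, uniformly spaced knot vector on [0, 1] (strictly increasing
    interior knots)."""
    n_interior = n_ctrl - degree - 1
    interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    return np.concatenate(
        [np.zeros(degree + 1), interior, np.ones(degree + 1)]
    )


def _clamped_bspline(control_points: np.ndarray) -> BSpline:
    t = _clamped_knots(len(control_points))
    return BSpline(t, control_points, SPLINE_DEGREE, extrapolate=False)


def evaluate_curve(strand: Strand, s) -> np.ndarray:
    """Point(s) on the strand's clamped cubic B-spline at parameter s in [0, 1].

    The clamped ends guarantee s=0 and s=1 return the end control points
    exactly.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0.0) or np.any(s_arr > 1.0):
        raise ParameterError(f"spline parameter must lie in [0, 1], got {s}")
    out = strand.spline(s_arr)
    # BSpline with extrapolate=False returns nan exactly at the right end of
    # the last interval on some paths; pin the clamped endpoints explicitly.
    if s_arr.ndim == 0:
        if s_arr == 1.0:
            return strand.control_points[-1].copy()
        if s_arr == 0.0:
            return strand.control_points[0].copy()
        return out
    out = np.array(out, dtype=float)
    out[s_arr == 0.0] = strand.control_points[0]
    out[s_arr == 1.0] = strand.control_points[-1]
    return out


def arc_length(strand: Strand, rtol: float = 1e-8) -> float:
    """Arc length of the strand's B-spline by adaptive Gauss quadrature.

    Gauss-Legendre panels are refined (doubled) until the relative change is
    below ``rtol``.
    """
    deriv = strand.spline.derivative()

    def _quad(n_panels: int) -> float:
        # 10-point Gauss-Legendre per panel
        x, w = np.polynomial.legendre.leggauss(10)
        edges = np.linspace(0.0, 1.0, n_panels + 1)
        a, b = edges[:-1], edges[1:]
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        pts = (mid[:, None] + half[:, None] * x[None, :]).ravel()
        speeds = np.linalg.norm(deriv(pts), axis=-1).reshape(n_panels, -1)
        return float(np.sum(half * (speeds * w).sum(axis=1)))

    n = max(4, len(strand.control_points))
    prev = _quad(n)
    for _ in range(12):
        n *= 2
        cur = _quad(n)
        if abs(cur - prev) <= rtol * max(abs(cur), 1.0):
            return cur
        prev = cur
    return prev


# ---------------------------------------------------------------------------
# Constitutive curves (vectorised; scalars in, scalars out)
# ---------------------------------------------------------------------------

def force_length(l_norm, width: float = 0.3):
    """Dimensionless active force-length curve FL (Gaussian bell).

    Maximum 1 at l_norm = 1, symmetric about the optimum, C-infinity smooth.
    """
    l_arr = np.asarray(l_norm, dtype=float)
    if np.any(l_arr <= 0.0):
        raise ParameterError(f"normalized length must be > 0, got {l_norm}")
    out = np.exp(-(((l_arr - 1.0) / width) ** 2))
    return out if l_arr.ndim else float(out)


def force_velocity(v_norm, curvature: float = 0.25, lengthening_gain: float = 0.4):
    """Dimensionless force-velocity curve FV.

    Shortening branch (v_norm < 0): Hill hyperbola (1+v)/(1-v/c), zero at the
    maximal shortening velocity v_norm = -1 and below.  Lengthening branch
    (v_norm > 0): saturating rise to 1 + lengthening_gain, with the branch
    half-constant chosen so the slope is continuous at v_norm = 0 (slope there
    is 1 + 1/c from the Hill branch).
    """
    v = np.asarray(v_norm, dtype=float)
    slope0 = 1.0 + 1.0 / curvature
    g = lengthening_gain
    half = g / slope0
    shortening = np.clip((1.0 + v) / (1.0 - v / curvature), 0.0, None)
    lengthening = 1.0 + g * v / (v + half)
    out = np.where(v < 0.0, shortening, lengthening)
    return out if v.ndim else float(out)


def passive_force(params, length: float, velocity: float = 0.0):
    """Passive tension (gf) of a contractile strand: exponential toe above the
    slack length plus linear passive viscosity, clamped at zero.

    ``params`` is a MuscleParams-like object (anatomy module)."""
    strain = (np.asarray(length, dtype=float) - params.passive_slack_length) / params.passive_slack_length
    elastic = np.where(
        strain > 0.0,
        params.passive_stiffness_scale * np.expm1(params.passive_toe_exponent * np.clip(strain, 0.0, None)),
        0.0,
    )
    total = np.clip(elastic + params.passive_damping * np.asarray(velocity, dtype=float), 0.0, None)
    return total if total.ndim else float(total)


def muscle_tension(strand_or_params, a: float, l: float, v: float = 0.0) -> StrandForceState:
    """Three-element Hill tension of a contractile strand.

    Parameters may be given as a :class:`Strand` (whose ``params`` are used)
    or a MuscleParams directly.  Returns the decomposed
    :class:`StrandForceState` with F_muscle = F_active + F_passive, all >= 0.
    """
    params = getattr(strand_or_params, "params", strand_or_params)
    if not 0.0 <= a <= 1.0:
        raise ParameterError(f"activation must lie in [0, 1], got {a}")
    if l <= 0.0:
        raise ParameterError(f"strand length must be > 0, got {l}")
    l_norm = l / params.optimal_fiber_length
    v_norm = v / params.max_shortening_velocity
    f_active = (
        a
        * params.max_isometric_force
        * force_length(l_norm, params.fl_width)
        * force_velocity(v_norm, params.fv_curvature, params.fv_lengthening_gain)
    )
    f_passive = passive_force(params, l, v)
    return StrandForceState(
        activation=a,
        length=l,
        velocity=v,
        f_active=float(f_active),
        f_passive=float(f_passive),
        f_muscle=float(f_active + f_passive),
    )


def elastic_tension(params: ElasticParams, length: float):
    """Tension (gf) of a non-contractile elastic strand.

    Zero at or below the rest length (strands cannot push); otherwise
    ``stiffness * strain^exponent``, continuous at the rest length.
    """
    l_arr = np.asarray(length, dtype=float)
    if np.any(l_arr <= 0.0):
        raise ParameterError(f"length must be > 0, got {length}")
    strain = np.clip((l_arr - params.rest_length) / params.rest_length, 0.0, None)
    out = params.stiffness * strain**params.exponent
    return out if l_arr.ndim else float(out)


def straight_strand(
    p0: Sequence[float],
    p1: Sequence[float],
    n_ctrl: int,
    kind: str,
    params: object,
    rest_length: float,
    node_mass: float = 0.1,
    attachments: tuple = ("fixed", "fixed"),
) -> Strand:
    """Convenience constructor: evenly spaced control points on the segment
    p0 -> p1."""
    pts = np.linspace(np.asarray(p0, float), np.asarray(p1, float), n_ctrl)
    return Strand(
        control_points=pts,
        node_masses=np.full(n_ctrl, node_mass),
        strand_kind=kind,
        params=params,
        rest_length=rest_length,
        attachments=attachments,
    )
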