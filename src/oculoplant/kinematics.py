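"""Rotation utilities: Fick gaze angles and fast quaternion arithmetic.

Gaze is specified as a Fick sequence: first a horizontal rotation about the
orbit's vertical (+Y) axis, then a vertical rotation about the rotated
horizontal axis.  Positive horizontal = abduction for the modelled right eye
(gaze toward +X); positive vertical = supraduction (gaze toward +Y).
Quaternions use scipy's [x, y, z, w] convention.
"""

from __future__ import annotations

import numpy as np

from .units import DEG2RAD, RAD2DEG

__all__ = [
    "fick_rotation",
    "gaze_from_rotation",
    "rotation_error_deg",
    "quat_identity",
    "quat_multiply",
    "quat_from_rotvec",
    "quat_to_matrix",
    "quat_normalize",
    "rotvec_from_matrix",
]


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def fick_rotation(gaze_h_deg: float, gaze_v_deg: float) -> np.ndarray:
    """Rotation matrix of a (horizontal, vertical) Fick gaze, zero torsion.

    R maps reference-pose (central gaze) points to rotated points; the gaze
    direction is R @ [0, 0, 1].
    """
    return _ry(gaze_h_deg * DEG2RAD) @ _rx(-gaze_v_deg * DEG2RAD)


def gaze_from_rotation(R: np.ndarray):
    """(horizontal, vertical) Fick angles in degrees of a globe rotation."""
    g = R @ np.array([0.0, 0.0, 1.0])
    v = np.arcsin(np.clip(g[1], -1.0, 1.0)) * RAD2DEG
    h = np.arctan2(g[0], g[2]) * RAD2DEG
    return float(h), float(v)


def rotvec_from_matrix(R: np.ndarray) -> np.ndarray:
    """Rotation vector (radians) of a rotation matrix (stable small-angle)."""
    tr = np.trace(R)
    cos_t = np.clip((tr - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(cos_t)
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if theta < 1e-8:
        return 0.5 * w
    if np.pi - theta < 1e-6:
        # near-pi fallback via the symmetric part
        A = (R + np.eye(3)) / 2.0
        axis = np.sqrt(np.clip(np.diag(A), 0.0, None))
        axis *= np.sign([w[0], w[1], w[2]]) + (np.sign(w) == 0)
        n = np.linalg.norm(axis)
        return theta * axis / (n if n > 0 else 1.0)
    return theta * w / (2.0 * np.sin(theta))


def rotation_error_deg(R_target: np.ndarray, R_current: np.ndarray) -> np.ndarray:
    """Rotation vector (degrees) carrying the current orientation onto the
    target, expressed in the orbit frame."""
    return rotvec_from_matrix(R_target @ R_current.T) * RAD2DEG


def gaze_direction_error_deg(R_target: np.ndarray, R_current: np.ndarray) -> np.ndarray:
    """Rotation vector (degrees) of the great-circle rotation carrying the
    current gaze *direction* onto the target gaze direction.

    Torsion about the line of sight is deliberately excluded: the controller
    servoes gaze direction only, while ocular torsion is restored passively
    by the orbital tissues.
    """
    z = np.array([0.0, 0.0, 1.0])
    g_cur = R_current @ z
    g_tgt = R_target @ z
    axis = np.cross(g_cur, g_tgt)
    n = np.linalg.norm(axis)
    angle = np.arctan2(n, np.clip(np.dot(g_cur, g_tgt), -1.0, 1.0))
    if n < 1e-12:
        return np.zeros(3)
    return (angle * RAD2DEG) * axis / n


# -- quaternions ([x, y, z, w]) ---------------------------------------------

def quat_identity() -> np.ndarray:
    return np.array([0.0, 0.0, 0.0, 1.0])


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    x1, y1, z1, w1 = q1
    x2, y2, z2, w2 = q2
    return np.array(
        [
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        ]
    )


def quat_from_rotvec(rv: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(rv)
    if theta < 1e-12:
        return np.array([rv[0] / 2.0, rv[1] / 2.0, rv[2] / 2.0, 1.0]) / np.sqrt(
            1.0 + theta**2 / 4.0
        )
    axis = rv / theta
    s = np.sin(theta / 2.0)
    return np.array([axis[0] * s, axis[1] * s, axis[2] * s, np.cos(theta / 2.0)])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    x, y, z, w = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_from_matrix(R: np.ndarray) -> np.ndarray:
    return quat_from_rotvec(rotvec_from_matrix(R))
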