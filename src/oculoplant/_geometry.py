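"""Small polyline/geometry helpers shared by anatomy and the plant builder."""

from __future__ import annotations

import numpy as np


def polyline_length(points) -> float:
    pts = np.asarray(points, float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def resample_polyline(waypoints, n: int) -> np.ndarray:
    """n points evenly spaced in arc length along a waypoint polyline."""
    pts = np.asarray(waypoints, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 3))
    for k, t in enumerate(targets):
        i = min(int(np.searchsorted(s, t, side="right")) - 1, len(seg) - 1)
        i = max(i, 0)
        w = (t - s[i]) / seg[i] if seg[i] > 0 else 0.0
        out[k] = (1.0 - w) * pts[i] + w * pts[i + 1]
    return out


def push_outside_sphere(points, center, radius: float) -> np.ndarray:
    """Radially project any point closer than ``radius`` to the sphere
    surface (used to route initial muscle paths over the sclera)."""
    pts = np.array(points, dtype=float)
    rel = pts - np.asarray(center, float)
    d = np.linalg.norm(rel, axis=1)
    inside = d < radius
    if np.any(inside):
        pts[inside] = center + rel[inside] * (radius / d[inside])[:, None]
    return pts


def wrapped_path(p0, p1, center, radius: float, n: int = 33) -> np.ndarray:
    """Shortest-ish path from p0 to p1 that stays outside the sphere: the
    straight chord with interior points projected to the surface, then
    re-spaced.  Endpoints are preserved."""
    pts = resample_polyline([p0, p1], n)
    pts[1:-1] = push_outside_sphere(pts[1:-1], center, radius)
    # re-space once so projection does not bunch nodes
    out = resample_polyline(pts, n)
    out[1:-1] = push_outside_sphere(out[1:-1], center, radius)
    return out


def sample_path_at(points, arc_positions) -> np.ndarray:
    """Points at given arc-length positions along a polyline."""
    pts = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    out = np.empty((len(arc_positions), 3))
    for k, t in enumerate(np.clip(arc_positions, 0.0, s[-1])):
        i = min(int(np.searchsorted(s, t, side="right")) - 1, len(seg) - 1)
        i = max(i, 0)
        w = (t - s[i]) / seg[i] if seg[i] > 0 else 0.0
        out[k] = (1.0 - w) * pts[i] + w * pts[i + 1]
    return out
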