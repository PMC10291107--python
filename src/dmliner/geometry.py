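"""Spherical-geometry helpers: unit vectors, great-circle distances,
distance to a great-circle arc segment, and rigid-body transforms."""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit_vector",
    "spherical_to_cartesian",
    "cartesian_to_spherical",
    "great_circle_angle",
    "arc_segment_angle",
    "rotation_about_z",
    "validate_rotation",
    "apply_rigid",
]


def spherical_to_cartesian(polar_deg, azimuth_deg, radius=1.0):
    """Unit-sphere convention: polar angle from +z, azimuth from +x (CCW)."""
    th = np.deg2rad(np.asarray(polar_deg, dtype=float))
    ph = np.deg2rad(np.asarray(azimuth_deg, dtype=float))
    st = np.sin(th)
    return np.stack(
        [radius * st * np.cos(ph), radius * st * np.sin(ph), radius * np.cos(th)],
        axis=-1,
    )


def cartesian_to_spherical(points, centre=None):
    """Return (radius mm, polar deg, azimuth deg in [0, 360)) about *centre*."""
    p = np.asarray(points, dtype=float)
    if centre is not None:
        p = p - np.asarray(centre, dtype=float)
    r = np.linalg.norm(p, axis=-1)
    with np.errstate(invalid="ignore"):
        polar = np.degrees(np.arccos(np.clip(p[..., 2] / np.where(r == 0, 1, r), -1, 1)))
    azimuth = np.degrees(np.arctan2(p[..., 1], p[..., 0])) % 360.0
    return r, polar, azimuth


def unit_vector(polar_deg, azimuth_deg):
    return spherical_to_cartesian(polar_deg, azimuth_deg, 1.0)


def great_circle_angle(u, v):
    """Angle in degrees between unit vectors; numerically stable near 0/180."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    cross = np.linalg.norm(np.cross(u, v), axis=-1)
    dot = np.sum(u * v, axis=-1)
    return np.degrees(np.arctan2(cross, dot))


def arc_segment_angle(u, a, b):
    """Angular distance (deg) from unit vectors *u* (N,3) to the great-circle
    arc segment from *a* to *b* (unit vectors).

    Uses the perpendicular distance to the great circle where the foot of
    the perpendicular lies within the segment, otherwise the distance to the
    nearer endpoint.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = np.cross(a, b)
    nn = np.linalg.norm(n)
    if nn < 1e-12:  # coincident (or antipodal) endpoints: point-like segment
        return great_circle_angle(u, a)
    n = n / nn
    sin_perp = np.clip(np.abs(u @ n), 0.0, 1.0)
    perp = np.degrees(np.arcsin(sin_perp))
    # foot of perpendicular on the great circle
    q = u - np.outer(u @ n, n)
    qn = np.linalg.norm(q, axis=-1)
    ok = qn > 1e-12
    q[ok] = q[ok] / qn[ok][:, None]
    seg = great_circle_angle(a, b)
    within = ok & (
        great_circle_angle(q, a) + great_circle_angle(q, b) <= seg + 1e-9
    )
    d_end = np.minimum(great_circle_angle(u, a), great_circle_angle(u, b))
    return np.where(within, perp, d_end)


def rotation_about_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def validate_rotation(rot: np.ndarray) -> np.ndarray:
    rot = np.asarray(rot, dtype=float)
    if rot.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9):
        raise ValueError("degenerate rotation: matrix is not orthonormal")
    if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-9):
        raise ValueError("degenerate rotation: determinant is not +1")
    return rot


def apply_rigid(points, rotation=None, translation=None):
    p = np.asarray(points, dtype=float)
    if rotation is not None:
        p = p @ validate_rotation(rotation).T
    if translation is not None:
        p = p + np.asarray(translation, dtype=float)
    return p
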