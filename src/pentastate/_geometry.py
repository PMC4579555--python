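"""Small rigid-body geometry helpers shared across modules.

All angles at this interface are degrees; lengths are Å.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def rotation_matrix(direction: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about ``direction`` by ``angle_deg``."""
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * unit(direction)).as_matrix()


def rotate_about_line(
    points: np.ndarray, point_on_line: np.ndarray, direction: np.ndarray, angle_deg: float
) -> np.ndarray:
    """Rotate ``points`` (N,3) about the line through ``point_on_line`` with ``direction``."""
    R = rotation_matrix(direction, angle_deg)
    p0 = np.asarray(point_on_line, dtype=float)
    return (np.asarray(points, dtype=float) - p0) @ R.T + p0


def foot_on_line(points: np.ndarray, point_on_line: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Perpendicular foot of each point on the line (N,3) -> (N,3)."""
    d = unit(direction)
    p0 = np.asarray(point_on_line, dtype=float)
    rel = np.atleast_2d(np.asarray(points, dtype=float) - p0)
    return p0 + np.outer(rel @ d, d)


def distance_to_line(points: np.ndarray, point_on_line: np.ndarray, direction: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    feet = foot_on_line(pts, point_on_line, direction)
    return np.linalg.norm(pts - feet, axis=1)


def polar_axis(omega_deg: float, phi_deg: float) -> np.ndarray:
    """Unit axis from polar rotation angles (omega from +z, phi azimuth in xy)."""
    om = np.deg2rad(omega_deg)
    ph = np.deg2rad(phi_deg)
    return np.array([np.sin(om) * np.cos(ph), np.sin(om) * np.sin(ph), np.cos(om)])
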