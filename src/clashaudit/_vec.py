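"""Small 3D vector-geometry helpers shared across modules."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, w = unit(a - b), unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral a-b-c-d in degrees, in (-180, 180]."""
    b0, b1, b2 = b - a, c - b, d - c
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m = np.cross(n1, unit(b1))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, theta: float, phi: float) -> np.ndarray:
    """NeRF placement: new atom D with |CD| = length, angle(B,C,D) = theta
    and dihedral(A,B,C,D) = phi (degrees)."""
    th = np.radians(theta)
    ph = np.radians(phi)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -length * np.cos(th),
        length * np.sin(th) * np.cos(ph),
        -length * np.sin(th) * np.sin(ph),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis_point: np.ndarray, axis_dir: np.ndarray,
                        angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix R and offset t such that x' = R @ (x - p) + p."""
    k = unit(axis_dir)
    t = np.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)
    return R, axis_point


def rotate_points(points: np.ndarray, axis_point: np.ndarray,
                  axis_dir: np.ndarray, angle_deg: float) -> np.ndarray:
    R, p = rotation_about_axis(axis_point, axis_dir, angle_deg)
    return (points - p) @ R.T + p


def branch_dihedral(theta_ab: float, theta_ac: float, theta_bc: float) -> float:
    """Dihedral separation (degrees) between two substituents B and C around a
    centre, given the three inter-substituent angles at the centre (spherical
    law of cosines).  Used to place a second branch so all three bond angles
    hit their targets exactly."""
    t_ab, t_ac, t_bc = map(np.radians, (theta_ab, theta_ac, theta_bc))
    cosphi = (np.cos(t_bc) - np.cos(t_ab) * np.cos(t_ac)) / (np.sin(t_ab) * np.sin(t_ac))
    return float(np.degrees(np.arccos(np.clip(cosphi, -1.0, 1.0))))


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points; returns (centroid, unit normal)."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    return centroid, vt[-1]
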