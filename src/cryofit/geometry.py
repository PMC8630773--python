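"""Internal-coordinate geometry helpers.

Atom placement from bond length / bond angle / dihedral (the NeRF
construction), dihedral measurement, rigid rotations, and RMSD — shared
by the synthetic-structure builder, the chi1 ring sweep, and the
stereochemistry restraints.
"""

from __future__ import annotations

import numpy as np

__all__ = ["place_internal", "dihedral", "bond_angle", "rotation_about_axis", "rmsd"]


def place_internal(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates.

    d is at distance ``bond`` from c, with angle b-c-d equal to
    ``angle_deg`` and dihedral a-b-c-d equal to ``dihedral_deg``.
    """
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm_n = np.linalg.norm(n)
    if norm_n < 1e-12:
        # colinear predecessors: any perpendicular works, dihedral origin arbitrary
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-12:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
        norm_n = np.linalg.norm(n)
    n /= norm_n
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            -bond * np.sin(theta) * np.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral angle a-b-c-d in degrees, in (-180, 180]."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.rad2deg(np.arctan2(y, x)))


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Coordinate RMSD between matched point sets (no superposition)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
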