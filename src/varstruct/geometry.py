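"""Low-level vector geometry: dihedrals, internal-coordinate placement, Kabsch.

Everything here is plain NumPy on 3-vectors; angles are degrees at the API
boundary and radians internally.
"""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = unit(np.asarray(a) - b), unit(np.asarray(c) - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed dihedral p1-p2-p3-p4 in degrees, in (-180, 180]."""
    b1 = np.asarray(p2) - p1
    b2 = np.asarray(p3) - p2
    b3 = np.asarray(p4) - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    d = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if d <= -180.0 else d


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, bond_angle: float, torsion: float) -> np.ndarray:
    """Natural-extension-reference-frame placement.

    Returns the point d with |c-d| = bond, angle(b,c,d) = bond_angle and
    dihedral(a,b,c,d) = torsion (degrees).
    """
    theta = np.radians(bond_angle)
    chi = np.radians(torsion)
    bc = unit(np.asarray(c) - b)
    n = unit(np.cross(np.asarray(b) - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(theta),
        np.sin(theta) * np.cos(chi),
        -np.sin(theta) * np.sin(chi),
    ])
    return np.asarray(c) + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking direction `a` onto direction `b` (Rodrigues)."""
    u, v = unit(np.asarray(a, dtype=float)), unit(np.asarray(b, dtype=float))
    c = float(np.dot(u, v))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite directions: rotate 180 deg about any perpendicular axis
        helper = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = unit(np.cross(u, helper))
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rigid superposition of `mobile` onto `target` (N x 3 each).

    Returns (rotation 3x3, translation 3, transformed mobile coordinates).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate arrays must both be N x 3")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t, (R @ P.T).T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a), np.asarray(b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
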