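"""Point-geometry primitives: dihedral measurement, its analytic gradient,
and internal-coordinate atom placement (NeRF).

All positions are 3-vectors in Å.  Dihedral angles follow the IUPAC sign
convention: cis = 0°, trans = 180°, sign by the right-hand rule about the
p2→p3 axis, range (−180°, 180°].
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError

_COLLINEAR_TOL = 1e-10


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Dihedral angle p1-p2-p3-p4 in degrees, in (−180, 180].

    Raises
    ------
    GeometryError
        If either bonded triple is (numerically) collinear or adjacent
        points coincide, in which case the angle is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise GeometryError(
            "dihedral undefined: collinear or coincident points "
            f"(|b1×b2|={np.linalg.norm(n1):.2e}, |b2×b3|={np.linalg.norm(n2):.2e})"
        )
    b2_hat = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2_hat))
    angle = np.degrees(np.arctan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def dihedral_gradient(p1, p2, p3, p4) -> np.ndarray:
    """Analytic gradient of the dihedral angle (radians) w.r.t. the four
    positions; shape (4, 3), units rad/Å.

    The gradient sums to zero (translation invariance) and has zero net
    torque about any origin (rotation invariance).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    m = np.cross(b1, b2)
    n = np.cross(b2, b3)
    m2 = float(np.dot(m, m))
    n2 = float(np.dot(n, n))
    if m2 < _COLLINEAR_TOL**2 or n2 < _COLLINEAR_TOL**2:
        raise GeometryError("dihedral gradient undefined: collinear points")
    lb2 = float(np.linalg.norm(b2))
    g1 = -(lb2 / m2) * m
    g4 = (lb2 / n2) * n
    d12 = float(np.dot(b1, b2)) / lb2**2
    d32 = float(np.dot(b3, b2)) / lb2**2
    g2 = -(1.0 + d12) * g1 + d32 * g4
    g3 = d12 * g1 - (1.0 + d32) * g4
    return np.array([g1, g2, g3, g4])


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D so that |C−D| = *bond*, angle(B,C,D) = *angle_deg* and
    dihedral(A,B,C,D) = *dihedral_deg* (IUPAC convention).

    The natural extension reference frame (NeRF) construction.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    norm_n = np.linalg.norm(n)
    if norm_n < _COLLINEAR_TOL:
        raise GeometryError("cannot place atom: reference frame is collinear")
    n_hat = n / norm_n
    m_hat = np.cross(n_hat, bc_hat)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc_hat + d_local[1] * m_hat + d_local[2] * n_hat


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray):
    """Optimal proper rotation + translation superposing *mobile* onto
    *reference* (both (n, 3), paired rows).

    Returns ``(R, t)`` with ``mobile @ R.T + t ≈ reference`` in the
    least-squares sense; ``det(R) = +1`` is enforced.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    return rot, trans


def wrap_angle(angle_deg):
    """Wrap angle(s) into (−180, 180]."""
    wrapped = -((-np.asarray(angle_deg, dtype=float) + 180.0) % 360.0) + 180.0
    return wrapped
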