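"""Small-vector geometry: distances, angles, dihedrals, internal-coordinate
atom placement. All coordinates are Cartesian angstroms."""

from __future__ import annotations

import math

import numpy as np

Vec = np.ndarray


def distance(a: Vec, b: Vec) -> float:
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def angle_deg(a: Vec, b: Vec, c: Vec) -> float:
    """Angle a-b-c in degrees, with b at the vertex."""
    u = np.asarray(a) - np.asarray(b)
    v = np.asarray(c) - np.asarray(b)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise ValueError("degenerate angle: coincident atoms")
    cosang = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def dihedral_deg(a: Vec, b: Vec, c: Vec, d: Vec) -> float:
    """Signed dihedral a-b-c-d in degrees (IUPAC sign convention)."""
    b0 = np.asarray(a) - np.asarray(b)
    b1 = np.asarray(c) - np.asarray(b)
    b2 = np.asarray(d) - np.asarray(c)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def place_atom(a: Vec, b: Vec, c: Vec, length: float, angle: float, torsion: float) -> Vec:
    """Place atom d from internal coordinates relative to the frame (a, b, c).

    d satisfies |c-d| = ``length``, angle(b, c, d) = ``angle`` degrees and
    dihedral(a, b, c, d) = ``torsion`` degrees (natural extension reference
    frame construction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        # colinear frame: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        norm = np.linalg.norm(n)
    n = n / norm
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * math.cos(ang),
            length * math.sin(ang) * math.cos(tor),
            length * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
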