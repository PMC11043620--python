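"""Internal-coordinate chain building and small vector helpers.

Backbone chains are grown atom by atom with the standard natural extension
reference frame (NeRF) construction: each new atom is placed from the three
previously placed atoms given a bond length, a bond angle and a torsion.
"""

from __future__ import annotations

import numpy as np

# Idealized backbone internal coordinates (Engh/Huber-like averages, Å / deg).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010

ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7

OMEGA_TRANS = 180.0

ALPHA_PHI = -57.0
ALPHA_PSI = -47.0


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` normalized to unit length."""
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize zero vector")
    return v / n


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D such that |CD| = bond, angle(B,C,D) = angle and the
    dihedral A-B-C-D equals ``torsion`` (both in degrees)."""
    theta = np.deg2rad(angle)
    chi = np.deg2rad(torsion)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p0 - p1
    b1 = unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = unit(a - b)
    v = unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> dict[str, np.ndarray]:
    """Build backbone N/CA/C coordinates for a chain with the given per-residue
    (phi, psi) torsions (degrees) and ideal bond geometry.

    phi[0] is unused (no preceding carbonyl); omega is held trans.
    Returns arrays of shape (n_res, 3) keyed by atom name, plus carbonyl O
    and amide H (H absent on the first residue => NaN row).
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != psi.shape or phi.ndim != 1:
        raise ValueError("phi and psi must be 1-D arrays of equal length")
    n_res = len(phi)
    if n_res < 1:
        raise ValueError("need at least one residue")

    N = np.empty((n_res, 3))
    CA = np.empty((n_res, 3))
    C = np.empty((n_res, 3))

    # Seed frame for residue 0.
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [BOND_N_CA, 0.0, 0.0]
    th = np.deg2rad(180.0 - ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([np.cos(th), np.sin(th), 0.0])

    for i in range(n_res - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi[i])
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi[i + 1])

    # Virtual next N after the last residue fixes the final carbonyl plane.
    n_virtual = place_atom(N[-1], CA[-1], C[-1], BOND_C_N, ANGLE_CA_C_N, psi[-1])
    n_next = np.vstack([N[1:], n_virtual])

    # Carbonyl O: sp2 carbon, O anti to the bisector of (CA, N_next).
    u_ca = (CA - C) / np.linalg.norm(CA - C, axis=1, keepdims=True)
    u_nn = (n_next - C) / np.linalg.norm(n_next - C, axis=1, keepdims=True)
    bis = u_ca + u_nn
    O = C - BOND_C_O * bis / np.linalg.norm(bis, axis=1, keepdims=True)

    # Amide H: on N, anti to the bisector of (C_prev, CA). First residue: NaN.
    H = np.full((n_res, 3), np.nan)
    if n_res > 1:
        u_cp = (C[:-1] - N[1:]) / np.linalg.norm(C[:-1] - N[1:], axis=1, keepdims=True)
        u_ca2 = (CA[1:] - N[1:]) / np.linalg.norm(CA[1:] - N[1:], axis=1, keepdims=True)
        bis_h = u_cp + u_ca2
        H[1:] = N[1:] - BOND_N_H * bis_h / np.linalg.norm(bis_h, axis=1, keepdims=True)

    return {"N": N, "CA": CA, "C": C, "O": O, "H": H}


def principal_axis_align(coords: np.ndarray, guide: np.ndarray | None = None) -> np.ndarray:
    """Rotate a coordinate set so its longest principal axis lies along z.

    ``guide`` (defaults to all coords) selects the rows used to define the
    axis; the same rotation is applied to every row of ``coords``.
    """
    pts = coords if guide is None else guide
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center)
    axis = vt[0]
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = np.dot(axis, z)
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return (coords - center) @ rot.T
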