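"""Internal-coordinate geometry shared by the backbone builder and side-chain grafting.

All distances in Angstrom, angles in degrees unless noted.
"""

from __future__ import annotations

import numpy as np

# Ideal peptide backbone internal coordinates (single authoritative table).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

# CB placement: 1.52 A from CA, tetrahedral N-CA-CB angle.
BOND_CA_CB = 1.52
ANGLE_N_CA_CB = 110.5


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given reference atoms A, B, C (NeRF construction).

    D is at distance ``bond`` from C, with angle B-C-D = ``angle_deg`` and
    dihedral A-B-C-D = ``dihedral_deg``.
    """
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # Degenerate (collinear references): pick any perpendicular.
        probe = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(probe, bc)) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        n = np.cross(probe, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
             bond: float = BOND_CA_CB, angle_deg: float = ANGLE_N_CA_CB) -> np.ndarray:
    """Place CB from the three backbone atoms with exact N-CA-CB angle.

    The direction is the in-plane bisector of the N and C bonds tilted out of
    plane; the out-of-plane sign fixes L-chirality.
    """
    u1 = n - ca
    u1 /= np.linalg.norm(u1)
    u2 = c - ca
    u2 /= np.linalg.norm(u2)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u2, u1)
    perp /= np.linalg.norm(perp)
    # cos(angle N-CA-CB) = cos(alpha) * dot(bis, u1); solve for tilt alpha.
    denom = float(np.dot(bis, u1))
    cos_t = np.cos(np.deg2rad(angle_deg)) / denom
    cos_t = float(np.clip(cos_t, -1.0, 1.0))
    alpha = np.arccos(cos_t)
    d = np.cos(alpha) * bis + np.sin(alpha) * perp
    return ca + bond * d


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.rad2deg(np.arctan2(y, x)))


def angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Bond angle p0-p1-p2 in degrees."""
    u = p0 - p1
    v = p2 - p1
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))
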