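"""Low-level peptide geometry: internal-coordinate chain building and ideal helices.

All lengths in Angstrom, all angles in degrees unless noted. Backbone
construction uses the natural extension reference frame (NeRF): each atom is
placed from the three preceding atoms plus a bond length, bond angle and
torsion. Canonical covalent parameters are the Engh & Huber values commonly
used by model-building software.
"""

from __future__ import annotations

import numpy as np

# Engh & Huber style backbone covalent geometry
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

# canonical alpha-helix torsions (rise ~1.5 A, ~100 deg/residue)
HELIX_PHI = -57.0
HELIX_PSI = -47.0
OMEGA_TRANS = 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given chain A-B-C, |C-D|, angle(B,C,D) and torsion(A,B,C,D)."""
    angle = np.deg2rad(angle)
    torsion = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral C-beta from backbone N/CA/C.

    Uses the standard fixed linear combination of the local backbone frame;
    the resulting CA-CB distance is 1.53 A and the placement is exactly
    rotation/translation-equivariant with its inputs.
    """
    b = ca - n
    c_vec = c - ca
    a = np.cross(b, c_vec)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * c_vec + ca


def build_backbone(phi_psi: list[tuple[float, float]]) -> dict[str, np.ndarray]:
    """Build an (n,3)-per-atom backbone (N, CA, C, O) from a phi/psi list.

    ``phi_psi[i]`` gives the torsions flanking residue i; phi of the first
    residue and psi-dependent placement of the final O use the listed values
    directly, so an all-helical list yields an ideal alpha-helix.
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))

    # seed residue 0 in a canonical local frame
    N[0] = np.array([0.0, 0.0, 0.0])
    CA[0] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(n_res):
        phi, psi = phi_psi[i]
        if i > 0:
            # N(i) from CA(i-1), C(i-1) with psi(i-1); CA(i) with omega; C(i) with phi(i)
            N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                              BOND_C_N, ANGLE_CA_C_N, phi_psi[i - 1][1])
            CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                               BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
            C[i] = place_atom(C[i - 1], N[i], CA[i],
                              BOND_CA_C, ANGLE_N_CA_C, phi)
        # carbonyl O: torsion N-CA-C-O = psi + 180
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def ideal_helix_backbone(n_res: int) -> dict[str, np.ndarray]:
    """Ideal alpha-helical backbone of ``n_res`` residues (N, CA, C, O, CB)."""
    bb = build_backbone([(HELIX_PHI, HELIX_PSI)] * n_res)
    bb["CB"] = np.array([virtual_cb(bb["N"][i], bb["CA"][i], bb["C"][i])
                         for i in range(n_res)])
    return bb


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Dominant principal direction of a point cloud (unit vector)."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 degrees: rotate about any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + k + k @ k * ((1 - c) / s**2)


def oriented_helix(n_res: int, center: np.ndarray, direction: np.ndarray) -> dict[str, np.ndarray]:
    """Ideal helix whose CA principal axis runs along ``direction`` (N to C),
    CA centroid at ``center``."""
    bb = ideal_helix_backbone(n_res)
    axis = principal_axis(bb["CA"])
    # orient N->C along +axis
    if np.dot(bb["CA"][-1] - bb["CA"][0], axis) < 0:
        axis = -axis
    rot = rotation_between(axis, np.asarray(direction, dtype=float))
    centroid = bb["CA"].mean(axis=0)
    out = {}
    for name, coords in bb.items():
        out[name] = (coords - centroid) @ rot.T + np.asarray(center, dtype=float)
    return out
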