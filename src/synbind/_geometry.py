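"""Low-level geometry: internal-coordinate chain building and rigid superposition.

All coordinates are in nanometres, angles in radians unless noted.
Functions broadcast over arbitrary leading (batch) dimensions so whole
ensembles can be built or superposed in one vectorised call.
"""
from __future__ import annotations

import numpy as np

# Ideal peptide-backbone internal coordinates (CHARMM-like equilibrium values).
BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_N = 0.1329
BOND_C_O = 0.1229
ANGLE_N_CA_C = np.deg2rad(111.2)
ANGLE_CA_C_N = np.deg2rad(116.2)
ANGLE_C_N_CA = np.deg2rad(121.7)
ANGLE_CA_C_O = np.deg2rad(120.8)
OMEGA_TRANS = np.pi


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def place_atom(a, b, c, bond, angle, torsion):
    """Place atom D given three predecessors so that |C-D| = bond,
    angle(B,C,D) = angle and dihedral(A,B,C,D) = torsion (NeRF).

    a, b, c: (..., 3) arrays; bond/angle/torsion scalars or (...) arrays.
    """
    bond = np.asarray(bond)[..., None]
    angle = np.asarray(angle)
    torsion = np.asarray(torsion)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = (
        -np.cos(angle)[..., None] * bc
        + (np.sin(angle) * np.cos(torsion))[..., None] * m
        + (np.sin(angle) * np.sin(torsion))[..., None] * n
    )
    return c + bond * d


def dihedral(p0, p1, p2, p3):
    """Signed dihedral angle (radians) for points with leading batch dims."""
    b0 = p0 - p1
    b1 = _unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    return np.arctan2(y, x)


def build_backbone(dihedrals_deg: np.ndarray) -> np.ndarray:
    """Build N/CA/C/O backbone coordinates from a (phi, psi) track.

    Parameters
    ----------
    dihedrals_deg : array, shape (..., n_residues, 2)
        Per-residue (phi, psi) in degrees. phi of the first residue is
        ignored (it has no preceding carbonyl). Leading dimensions are
        treated as independent frames.

    Returns
    -------
    array, shape (..., 4 * n_residues, 3)
        Coordinates in nm, atoms ordered N, CA, C, O per residue, with
        ideal bond lengths/angles and trans peptide bonds.
    """
    dih = np.deg2rad(np.asarray(dihedrals_deg, dtype=np.float64))
    if dih.ndim < 2 or dih.shape[-1] != 2:
        raise ValueError("dihedral track must have shape (..., n_residues, 2)")
    batch = dih.shape[:-2]
    n_res = dih.shape[-2]
    phi = dih[..., 0]
    psi = dih[..., 1]

    coords = np.empty(batch + (n_res, 4, 3), dtype=np.float64)
    n0 = np.zeros(batch + (3,))
    ca0 = np.zeros(batch + (3,))
    ca0[..., 0] = BOND_N_CA
    c0 = ca0 + BOND_CA_C * np.array(
        [np.cos(np.pi - ANGLE_N_CA_C), np.sin(np.pi - ANGLE_N_CA_C), 0.0]
    )
    coords[..., 0, 0, :] = n0
    coords[..., 0, 1, :] = ca0
    coords[..., 0, 2, :] = c0

    for i in range(1, n_res):
        n_prev = coords[..., i - 1, 0, :]
        ca_prev = coords[..., i - 1, 1, :]
        c_prev = coords[..., i - 1, 2, :]
        n_i = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi[..., i - 1])
        ca_i = place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        c_i = place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi[..., i])
        coords[..., i, 0, :] = n_i
        coords[..., i, 1, :] = ca_i
        coords[..., i, 2, :] = c_i
        # carbonyl O of the previous residue, anti to the new amide N
        coords[..., i - 1, 3, :] = place_atom(
            n_prev, ca_prev, c_prev, BOND_C_O, ANGLE_CA_C_O, psi[..., i - 1] - np.pi
        )
    last = n_res - 1
    coords[..., last, 3, :] = place_atom(
        coords[..., last, 0, :],
        coords[..., last, 1, :],
        coords[..., last, 2, :],
        BOND_C_O,
        ANGLE_CA_C_O,
        psi[..., last] - np.pi,
    )
    return coords.reshape(batch + (4 * n_res, 3))


def _ca_ca_virtual_bond() -> float:
    """CA(i)-CA(i+1) distance implied by the ideal trans geometry."""
    xyz = build_backbone(np.array([[-120.0, 120.0], [-120.0, 120.0]]))
    return float(np.linalg.norm(xyz[5] - xyz[1]))


CA_CA_VIRTUAL_NM = _ca_ca_virtual_bond()


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation mapping centred P onto centred Q.

    P, Q: (..., n, 3), already centred. Returns (..., 3, 3) rotation
    matrices with det = +1 (reflections are corrected away).
    """
    H = np.swapaxes(P, -1, -2) @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.swapaxes(Vt, -1, -2) @ np.swapaxes(U, -1, -2)))
    D = np.zeros(H.shape[:-2] + (3, 3))
    D[..., 0, 0] = 1.0
    D[..., 1, 1] = 1.0
    D[..., 2, 2] = d
    return np.swapaxes(Vt, -1, -2) @ D @ np.swapaxes(U, -1, -2)


def superposed_rmsd(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Minimal RMSD between point sets after optimal rigid superposition.

    X, Y: (..., n, 3). Batched over leading dimensions; returns (...)
    RMSD in the same length unit as the inputs.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape[-2:] != Y.shape[-2:]:
        raise ValueError(
            f"point sets differ in shape: {X.shape[-2:]} vs {Y.shape[-2:]}"
        )
    Xc = X - X.mean(axis=-2, keepdims=True)
    Yc = Y - Y.mean(axis=-2, keepdims=True)
    R = kabsch_rotation(Xc, Yc)
    diff = Xc @ np.swapaxes(R, -1, -2) - Yc
    return np.sqrt(np.mean(np.sum(diff * diff, axis=-1), axis=-1))


def rigid_transform_from_triads(old_pts: np.ndarray, new_pts: np.ndarray):
    """Rigid transform (R, t) mapping the 3-point triad old_pts onto new_pts.

    Both are (3, 3) arrays of points. Apply as x @ R.T + t.
    """
    oc = old_pts.mean(axis=0)
    nc = new_pts.mean(axis=0)
    R = kabsch_rotation(old_pts - oc, new_pts - nc)
    # kabsch maps centred old onto centred new as p @ R.T
    t = nc - oc @ R.T
    return R, t
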