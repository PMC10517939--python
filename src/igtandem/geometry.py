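"""Low-level backbone geometry: dihedrals, internal-coordinate chain building,
rigid superposition.

These primitives underlie torsion measurement, the synthetic-fixture
generators and all RMSD/TM-score computations.  Superposition is delegated to
scipy's Kabsch solver (``Rotation.align_vectors``); everything else is plain
numpy.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

# Ideal backbone internal coordinates (Engh-Huber-like values, Å / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
BOND_N_H = 1.01

# Ideal torsions per ABEGO letter used by the connector builder.
ABEGO_TORSIONS = {
    "A": (-57.0, -47.0),
    "B": (-120.0, 130.0),
    "G": (60.0, 40.0),
    "E": (60.0, -130.0),
}


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Bond angle p0-p1-p2 in degrees."""
    u = p0 - p1
    v = p2 - p1
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, bond_angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position atom d with given internal coordinates
    relative to the chain a-b-c (angle at c, torsion about b-c)."""
    ang = np.radians(bond_angle)
    tor = np.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(ang),
                  bond * np.sin(ang) * np.cos(tor),
                  bond * np.sin(ang) * np.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(torsions: list[tuple[float, float, float]],
                   start: np.ndarray | None = None,
                   anchor_psi: float = 135.0,
                   anchor_omega: float = 180.0) -> dict[str, np.ndarray]:
    """Build an ideal-geometry backbone from per-residue (phi, psi, omega).

    phi of the first residue and psi/omega of the last are not realized in
    the coordinates (chain-terminal torsions are undefined); they are accepted
    so that round trips with measured torsion lists are direct.

    ``start`` optionally gives seed coordinates as a (3, 3) array of an
    anchor residue's (N, CA, C); the new chain then continues from that
    residue through a peptide bond using ``anchor_psi`` / ``anchor_omega``
    for the anchor's exit torsions.
    Returns arrays N, CA, C, O of shape (n, 3).
    """
    n = len(torsions)
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    if start is None:
        N[0] = [0.0, 0.0, 0.0]
        CA[0] = [BOND_N_CA, 0.0, 0.0]
        a = np.radians(ANGLE_N_CA_C)
        C[0] = CA[0] + [BOND_CA_C * np.cos(np.pi - a), BOND_CA_C * np.sin(np.pi - a), 0.0]
    else:
        pn, pca, pc = (np.asarray(p, dtype=float) for p in start)
        N[0] = place_atom(pn, pca, pc, BOND_C_N, ANGLE_CA_C_N, anchor_psi)
        CA[0] = place_atom(pca, pc, N[0], BOND_N_CA, ANGLE_C_N_CA, anchor_omega)
        C[0] = place_atom(pc, N[0], CA[0], BOND_CA_C, ANGLE_N_CA_C, torsions[0][0])
    for i in range(1, n):
        phi_i = torsions[i][0]
        psi_prev = torsions[i - 1][1]
        omega_prev = torsions[i - 1][2]
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, omega_prev)
        C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi_i)
    for i in range(n):
        # carbonyl O is anti to the next amide N, i.e. at torsion psi - 180
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, torsions[i][1] - 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def amide_hydrogen(n_prev_c: np.ndarray, n_pos: np.ndarray, ca_pos: np.ndarray) -> np.ndarray:
    """Reconstruct the amide H on the bisector of (C_prev->N, CA->N) at 1.01 Å."""
    u = n_pos - n_prev_c
    u = u / np.linalg.norm(u)
    v = n_pos - ca_pos
    v = v / np.linalg.norm(v)
    b = u + v
    b = b / np.linalg.norm(b)
    return n_pos + BOND_N_H * b


def superpose(coords_a: np.ndarray, coords_b: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid superposition of B onto A.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords_b @ rotation.T + translation`` best matches ``coords_a``.
    The rotation is proper (det = +1).  Requires equal-length point sets
    with >= 3 points.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"superpose: length mismatch {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("superpose: need at least 3 points")
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    rot, rssd = Rotation.align_vectors(a - ca, b - cb)
    R = rot.as_matrix()
    t = ca - R @ cb
    rmsd = float(rssd) / np.sqrt(len(a))
    return R, t, rmsd


def rmsd_fixed(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD without superposition (frozen frame)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rmsd_fixed: length mismatch")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def apply_rigid(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ np.asarray(rotation).T + np.asarray(translation)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    return Rotation.random(random_state=rng).as_matrix()
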