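"""Backbone geometry primitives.

Internal-coordinate (NeRF) chain building, four-point dihedrals, bond
angles, and Kabsch least-squares superposition.  Everything downstream
(region annotation, the cluster dihedral metric, CCD loop closure, the
coarse score) works on plain ``(3,)``/``(n, 3)`` float64 arrays produced
here.

Bond lengths and angles follow standard peptide values (Engh & Huber
style means); omega defaults to trans (180 deg).
"""

from __future__ import annotations

import math

import numpy as np

# Ideal peptide backbone internal coordinates (lengths in Angstrom,
# angles in degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.1


def normalize(v: np.ndarray) -> np.ndarray:
    n = math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    if n < 1e-12:
        raise ValueError("cannot normalize zero-length vector")
    return v / n


def cross3(a, b) -> np.ndarray:
    """Cross product of two 3-vectors without numpy dispatch overhead."""
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees, in (0, 180)."""
    u = normalize(np.asarray(a, float) - np.asarray(b, float))
    w = normalize(np.asarray(c, float) - np.asarray(b, float))
    cosang = min(1.0, max(-1.0, float(u @ w)))
    return math.degrees(math.acos(cosang))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral of four points, degrees in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = cross3(b0, b1)
    n2 = cross3(b1, b2)
    m1 = cross3(normalize(b1), n1)
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = math.degrees(math.atan2(y, x))
    # map -180 -> 180 so the range is (-180, 180]
    return 180.0 if ang <= -180.0 + 1e-12 else ang


def wrap_angle(theta: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    t = (float(theta) + 180.0) % 360.0 - 180.0
    return 180.0 if t == -180.0 else t


def angular_difference(a: float, b: float) -> float:
    """Smallest absolute difference between two angles, degrees in [0, 180]."""
    return abs(wrap_angle(a - b))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom d given three predecessors a-b-c.

    Returns d such that |c-d| = bond, angle(b, c, d) = angle_deg and
    dihedral(a, b, c, d) = torsion_deg.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = normalize(c - b)
    n = normalize(cross3(b - a, bc))
    m = cross3(n, bc)
    d0 = -bond * math.cos(ang)
    sin_ang = math.sin(ang)
    d1 = bond * sin_ang * math.cos(tor)
    d2 = bond * sin_ang * math.sin(tor)
    return c + d0 * bc + d1 * m + d2 * n


def build_backbone(torsions: np.ndarray) -> np.ndarray:
    """Build an ideal-geometry backbone from (phi, psi, omega) torsions.

    ``torsions`` is an (n, 3) array of per-residue (phi, psi, omega) in
    degrees.  phi of the first residue is ignored (undefined at the
    N-terminus); omega[i] is the peptide torsion leading into residue i.
    Returns an (n, 4, 3) array of N, CA, C, O coordinates.  To continue
    an existing chain use :func:`extend_backbone`.
    """
    torsions = np.asarray(torsions, float)
    n_res = len(torsions)
    out = np.zeros((n_res, 4, 3))
    # canonical frame for the first residue
    out[0, 0] = np.array([0.0, 0.0, 0.0])                      # N
    out[0, 1] = np.array([BOND_N_CA, 0.0, 0.0])                # CA
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    out[0, 2] = out[0, 1] + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])

    for i in range(n_res):
        if i > 0:
            n_i = place_atom(out[i - 1, 0], out[i - 1, 1], out[i - 1, 2],
                             BOND_C_N, ANGLE_CA_C_N, torsions[i - 1, 1])
            ca_i = place_atom(out[i - 1, 1], out[i - 1, 2], n_i,
                              BOND_N_CA, ANGLE_C_N_CA, torsions[i, 2])
            c_i = place_atom(out[i - 1, 2], n_i, ca_i,
                             BOND_CA_C, ANGLE_N_CA_C, torsions[i, 0])
            out[i, 0], out[i, 1], out[i, 2] = n_i, ca_i, c_i
        # carbonyl O from psi: O is anti to the next N
        psi = torsions[i, 1]
        out[i, 3] = place_atom(out[i, 0], out[i, 1], out[i, 2],
                               BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    return out


def extend_backbone(seed_n: np.ndarray, seed_ca: np.ndarray, seed_c: np.ndarray,
                    seed_psi: float, torsions: np.ndarray) -> np.ndarray:
    """Continue a chain from anchor atoms (N, CA, C of the previous residue).

    ``seed_psi`` is the psi torsion of the anchor residue (it fixes the
    placement of the first appended N).  ``torsions`` is (n, 3)
    (phi, psi, omega) for the appended residues; omega[i] is the peptide
    torsion leading into residue i.  Returns (n, 4, 3) N/CA/C/O.
    """
    torsions = np.asarray(torsions, float)
    n_res = len(torsions)
    out = np.zeros((n_res, 4, 3))
    prev = (np.asarray(seed_n, float), np.asarray(seed_ca, float),
            np.asarray(seed_c, float))
    prev_psi = float(seed_psi)
    for i in range(n_res):
        n_i = place_atom(prev[0], prev[1], prev[2],
                         BOND_C_N, ANGLE_CA_C_N, prev_psi)
        ca_i = place_atom(prev[1], prev[2], n_i,
                          BOND_N_CA, ANGLE_C_N_CA, torsions[i, 2])
        c_i = place_atom(prev[2], n_i, ca_i,
                         BOND_CA_C, ANGLE_N_CA_C, torsions[i, 0])
        o_i = place_atom(n_i, ca_i, c_i,
                         BOND_C_O, ANGLE_CA_C_O, torsions[i, 1] + 180.0)
        out[i] = [n_i, ca_i, c_i, o_i]
        prev = (n_i, ca_i, c_i)
        prev_psi = torsions[i, 1]
    return out


def build_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal C-beta position from backbone N, CA, C (tetrahedral)."""
    return place_atom(n, c, ca, 1.521, 110.4, -122.6)


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``target``.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("kabsch expects matching (n, 3) arrays")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ np.asarray(rotation, float).T + translation


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rotation_about_axis(point: np.ndarray, axis: np.ndarray, theta_rad: float):
    """Rotation matrix + translation for a rotation about a line.

    The line passes through ``point`` with direction ``axis``.
    Returns (R, t) so that x -> R @ x + t.
    """
    u = normalize(np.asarray(axis, float))
    p = np.asarray(point, float)
    c, s = math.cos(theta_rad), math.sin(theta_rad)
    ux, uy, uz = u
    R = np.array([
        [c + ux * ux * (1 - c), ux * uy * (1 - c) - uz * s, ux * uz * (1 - c) + uy * s],
        [uy * ux * (1 - c) + uz * s, c + uy * uy * (1 - c), uy * uz * (1 - c) - ux * s],
        [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s, c + uz * uz * (1 - c)],
    ])
    t = p - R @ p
    return R, t


def ccd_optimal_angle(axis_a: np.ndarray, axis_b: np.ndarray,
                      moving: np.ndarray, targets: np.ndarray) -> float:
    """Closed-form optimal rotation angle for one CCD step (radians).

    Rotating ``moving`` atoms about the axis a->b, choose the angle that
    minimizes the summed squared distance to ``targets``.
    """
    u = normalize(np.asarray(axis_b, float) - np.asarray(axis_a, float))
    a = np.asarray(axis_a, float)
    m = np.asarray(moving, float)
    t = np.asarray(targets, float)
    rel = m - a
    along = rel @ u
    o = a + np.outer(along, u)           # projections on the axis
    r = m - o
    tprime = t - o
    s = np.empty_like(r)
    s[:, 0] = u[1] * r[:, 2] - u[2] * r[:, 1]
    s[:, 1] = u[2] * r[:, 0] - u[0] * r[:, 2]
    s[:, 2] = u[0] * r[:, 1] - u[1] * r[:, 0]
    num = float(np.sum(tprime * s))
    den = float(np.sum(tprime * r))
    if abs(num) < 1e-14 and abs(den) < 1e-14:
        return 0.0
    return float(np.arctan2(num, den))
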