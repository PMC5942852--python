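"""Reduced side-chain representation.

Side chains are modeled as an ideal C-beta plus a single per-type
pseudo-centroid sphere (atom name ``CEN``) placed along the CA->CB
direction.  The table gives, per amino-acid type, the CA->centroid
distance and the centroid sphere radius (both Angstrom, rough averages
over rotamers).  Glycine has neither CB nor centroid.

Discrete side-chain "states" for packing are alternative centroid
placements obtained by tilting the CA->CB direction; they stand in for
rotamers at this resolution.
"""

from __future__ import annotations

import numpy as np

from . import geometry

#: aa -> (CA->centroid distance, centroid radius)
CENTROID_PARAMS = {
    "A": (1.53, 1.8), "R": (4.10, 2.3), "N": (2.50, 2.2), "D": (2.48, 2.2),
    "C": (2.07, 2.1), "Q": (3.10, 2.3), "E": (3.10, 2.3), "G": (0.00, 0.0),
    "H": (3.00, 2.4), "I": (2.30, 2.4), "L": (2.60, 2.4), "K": (3.50, 2.3),
    "M": (3.20, 2.4), "F": (3.40, 2.5), "P": (1.88, 2.2), "S": (1.70, 1.9),
    "T": (1.93, 2.1), "W": (3.90, 2.6), "Y": (3.60, 2.6), "V": (1.97, 2.2),
}

#: tilt angles (deg) of the centroid direction used as discrete states
STATE_TILTS = (0.0, 15.0, -15.0)


def build_reduced_sidechain(residue, state: int = 0) -> None:
    """(Re)build CB and CEN for a residue in place.

    ``state`` selects one of the discrete tilt states.  Glycine gets no
    side-chain atoms; a pre-existing SG (cysteine disulfide partner) is
    preserved.
    """
    residue.atoms.pop("CB", None)
    residue.atoms.pop("CEN", None)
    if residue.aa == "G":
        return
    n, ca, c = (residue.atoms[a] for a in ("N", "CA", "C"))
    cb = geometry.build_cb(n, ca, c)
    residue.atoms["CB"] = cb
    dist, radius = CENTROID_PARAMS[residue.aa]
    if radius <= 0:
        return
    direction = (cb - ca) / np.linalg.norm(cb - ca)
    tilt = STATE_TILTS[state % len(STATE_TILTS)]
    if tilt:
        axis = np.cross(direction, c - ca)
        axis_norm = np.linalg.norm(axis)
        if axis_norm > 1e-9:
            rot, trans = geometry.rotation_about_axis(
                ca, axis / axis_norm, np.radians(tilt))
            direction = rot @ direction
    residue.atoms["CEN"] = ca + dist * direction


def n_states(aa: str) -> int:
    """Number of discrete side-chain states for a residue type."""
    return 1 if aa == "G" else len(STATE_TILTS)


def set_residue_type(residue, aa: str, state: int = 0) -> None:
    """Mutate a residue's type and rebuild its reduced side chain."""
    residue.aa = aa
    build_reduced_sidechain(residue, state)
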