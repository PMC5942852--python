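"""CDR canonical-cluster toolkit.

Dihedral-space distance between CDR conformations, nearest-centroid
cluster assignment, outlier flagging and H3 kink classification.

The metric operates on per-residue (phi, psi) pairs (omega is matched
as cis/trans metadata, not part of the metric).  The default distance
is the squared-chord form d^2 = sum over angles of 2*(1 - cos(dtheta)),
reported on a per-angle-average scale converted back to degrees via
arccos(1 - d2_avg/2); a plain mean absolute angular difference is
available as a config switch.  A CDR further than 40 degrees (or
1.5 A backbone RMSD) from every centroid is an outlier -- this rule is
not applied to H3, which does not cluster well beyond short lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .errors import MetricError

#: Outlier thresholds: strictly greater than either flags an outlier.
OUTLIER_DISTANCE_DEG = 40.0
OUTLIER_RMSD_A = 1.5

#: |CA-CA-CA-CA pseudo-dihedral| at or below this is a kinked H3 base.
KINK_THRESHOLD_DEG = 90.0


@dataclass(frozen=True)
class DihedralVector:
    """Ordered (phi, psi) pairs of one CDR, degrees; omega kept aside."""

    angles: tuple  # ((phi, psi), ...) in degrees
    omegas: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "angles",
                           tuple((float(p), float(s)) for p, s in self.angles))
        object.__setattr__(self, "omegas", tuple(float(o) for o in self.omegas))

    @property
    def length(self) -> int:
        return len(self.angles)

    def flat(self) -> np.ndarray:
        return np.asarray(self.angles, float).ravel()

    @classmethod
    def from_phi_psi(cls, phi, psi, omega=None) -> "DihedralVector":
        return cls(tuple(zip(phi, psi)), tuple(omega) if omega is not None else ())


@dataclass(frozen=True)
class ClusterCentroid:
    """A canonical-cluster centroid, named ``<CDR>-<length>-<index>``."""

    cluster_id: str
    cdr: str
    length: int
    centroid_dihedrals: DihedralVector
    gene: str = "heavy"  # heavy | kappa | lambda

    def __post_init__(self):
        encoded = cluster_length(self.cluster_id)
        if encoded is not None and encoded != self.centroid_dihedrals.length:
            raise MetricError(
                f"cluster id {self.cluster_id} encodes length {encoded} but "
                f"centroid has {self.centroid_dihedrals.length} residues")


@dataclass
class ClusterAssignment:
    cluster_id: str
    distance_deg: float
    rmsd_A: float | None = None
    outlier: bool = False


def cluster_length(cluster_id: str) -> int | None:
    """Length encoded in a cluster id like ``L3-9-cis7-1`` (-> 9)."""
    parts = cluster_id.split("-")
    if len(parts) < 2:
        return None
    try:
        return int(parts[1])
    except ValueError:
        return None


def dihedral_distance(a: DihedralVector, b: DihedralVector,
                      form: str = "squared_chord") -> float:
    """Average per-angle dihedral distance between two CDRs, degrees.

    ``squared_chord`` (default): d2 = mean over angles of 2*(1-cos dtheta),
    mapped back to degrees via arccos(1 - d2/2), i.e. the angle whose
    chord equals the RMS chord of the per-angle differences.
    ``mean_abs``: plain circular mean absolute difference.
    """
    if a.length != b.length:
        raise MetricError(
            f"length mismatch: {a.length} vs {b.length}")
    da = np.radians(a.flat() - b.flat())
    if form == "squared_chord":
        d2 = float(np.mean(2.0 * (1.0 - np.cos(da))))
        return float(np.degrees(np.arccos(np.clip(1.0 - d2 / 2.0, -1.0, 1.0))))
    if form == "mean_abs":
        wrapped = np.abs(np.degrees(np.arctan2(np.sin(da), np.cos(da))))
        return float(np.mean(wrapped))
    raise MetricError(f"unknown metric form {form!r}")


def assign_cluster(cdr: DihedralVector, centroids, cdr_type: str | None = None,
                   form: str = "squared_chord") -> ClusterAssignment:
    """Nearest matching centroid (same CDR type and length).

    Ties in distance break to the lexicographically smaller cluster id.
    """
    candidates = [c for c in centroids
                  if c.length == cdr.length
                  and (cdr_type is None or c.cdr == cdr_type)]
    if not candidates:
        raise MetricError(
            f"no centroid of type {cdr_type} and length {cdr.length}")
    best = min(candidates,
               key=lambda c: (dihedral_distance(cdr, c.centroid_dihedrals, form),
                              c.cluster_id))
    assignment = ClusterAssignment(
        cluster_id=best.cluster_id,
        distance_deg=dihedral_distance(cdr, best.centroid_dihedrals, form))
    if cdr_type is not None:
        assignment.outlier = flag_outlier(assignment, cdr_type)
    return assignment


def flag_outlier(assignment: ClusterAssignment, cdr: str) -> bool:
    """True iff distance > 40 deg or RMSD > 1.5 A; never for H3.

    Thresholds are strict inequalities: a CDR at exactly 40 deg /
    1.5 A is still a cluster member.
    """
    if cdr == "H3":
        return False
    if assignment.distance_deg > OUTLIER_DISTANCE_DEG:
        return True
    if assignment.rmsd_A is not None and assignment.rmsd_A > OUTLIER_RMSD_A:
        return True
    return False


def classify_h3_kink(ca_coords, threshold_deg: float = KINK_THRESHOLD_DEG) -> str:
    """Kinked vs extended H3 base from the CA pseudo-dihedral.

    ``ca_coords`` are four consecutive CA positions: the last three H3
    residues followed by the conserved tryptophan after H3.  A
    pseudo-dihedral near 0 marks the kink; |dihedral| <= threshold
    (inclusive) classifies as kinked.
    """
    ca = np.asarray(ca_coords, float)
    if ca.shape != (4, 3):
        raise MetricError("classify_h3_kink needs exactly four CA positions")
    pseudo = geometry.dihedral(*ca)
    return "kinked" if abs(pseudo) <= threshold_deg else "extended"


def validate_cis_labels(cluster_id: str, omegas) -> None:
    """Warn when omega torsions disagree with cis annotations in the id.

    A ``cisN`` token in the cluster id promises a cis peptide bond
    leading into residue N (1-based).  Labels are metadata, not
    recomputed; this check only raises a warning on disagreement.
    """
    omegas = list(omegas)
    cis_positions = set()
    for token in cluster_id.split("-"):
        if token.startswith("cis"):
            for part in token[3:].split(","):
                if part.isdigit():
                    cis_positions.add(int(part))
    for pos in range(1, len(omegas) + 1):
        is_cis = abs(geometry.wrap_angle(omegas[pos - 1])) < 90.0
        if is_cis != (pos in cis_positions):
            warnings.warn(
                f"omega at position {pos} ({omegas[pos - 1]:.0f} deg) "
                f"disagrees with cis annotation of {cluster_id}",
                stacklevel=2)


def circular_mean_degrees(angles, axis=0) -> np.ndarray:
    """Mean direction of angles in degrees (fixture centroid helper)."""
    rad = np.radians(np.asarray(angles, float))
    return np.degrees(np.arctan2(np.mean(np.sin(rad), axis=axis),
                                 np.mean(np.cos(rad), axis=axis)))
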