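"""Antibody complex representation, PDB I/O and region annotation.

The in-memory model is deliberately small: a complex is an ordered set
of chains, each a list of :class:`Residue` objects carrying backbone
(and optional reduced side-chain) coordinates plus a framework
numbering label.  Chain roles (heavy / light / antigen) are supplied by
the caller -- there is no sequence-based chain typing and no
renumbering engine; input structures must already carry aligned
numbering labels (AHo-style).

CDR regions are located by label windows in a configurable
:class:`RegionBoundaryTable`.  The shipped defaults are AHo-style
windows (CDR1 27-40, CDR2 58-68, CDR3 107-138) plus the DE loop at
labels 82-89, which is treated as an honorary CDR (L4/H4).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import gemmi
import numpy as np

from . import geometry
from .errors import AnnotationError, DihedralError, FormatError

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: CA-CA distance beyond which consecutive residues are a chain break.
CHAIN_BREAK_CA_CA = 4.5

CDR_REGIONS = ("L1", "L2", "L3", "H1", "H2", "H3")
LOOP_REGIONS = CDR_REGIONS + ("L4", "H4")


@dataclass
class Residue:
    """One residue: identity, numbering label and heavy-atom coordinates.

    ``atoms`` maps atom name to a (3,) float array.  Reduced side chains
    use ``CB`` plus a per-type pseudo-centroid atom ``CEN``; cysteines
    may carry a real ``SG``.
    """

    chain_id: str
    seq_position: int
    number: int
    icode: str = ""
    aa: str = "G"
    atoms: dict = field(default_factory=dict)
    region: str = "framework"
    chain_break: bool = False

    @property
    def number_label(self) -> str:
        return f"{self.number}{self.icode}"

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))

    def backbone(self) -> np.ndarray:
        """(4, 3) N/CA/C/O array."""
        return np.array([self.atoms[a] for a in BACKBONE_ATOMS])

    def heavy_coords(self) -> np.ndarray:
        return np.array(list(self.atoms.values()))

    def copy(self) -> "Residue":
        """Copy sharing the (immutable-by-convention) atom arrays.

        Coordinate updates throughout the package assign fresh arrays
        into ``atoms`` rather than mutating in place, so sharing is
        safe and keeps structure copies cheap.
        """
        return Residue(self.chain_id, self.seq_position, self.number,
                       self.icode, self.aa, dict(self.atoms),
                       self.region, self.chain_break)


@dataclass(frozen=True)
class RegionBoundaryTable:
    """Label windows (inclusive) locating CDRs within antibody chains.

    Windows apply to the integer part of the numbering label; the same
    windows are used for heavy and light chains (CDR1/CDR2/CDR3 plus the
    DE loop), as in aligned numbering schemes.
    """

    cdr1: tuple = (27, 40)
    cdr2: tuple = (58, 68)
    cdr3: tuple = (107, 138)
    de_loop: tuple = (82, 89)

    def __post_init__(self):
        windows = sorted([self.cdr1, self.cdr2, self.de_loop, self.cdr3])
        for (a_lo, a_hi), (b_lo, b_hi) in zip(windows, windows[1:]):
            if a_hi >= b_lo:
                raise AnnotationError(
                    f"overlapping region windows {a_lo}-{a_hi} and {b_lo}-{b_hi}")

    def region_for(self, number: int, role: str) -> str:
        prefix = {"heavy": "H", "light": "L"}.get(role)
        if prefix is None:
            return "antigen"
        for idx, (lo, hi) in enumerate(
                (self.cdr1, self.cdr2, self.de_loop, self.cdr3)):
            if lo <= number <= hi:
                return prefix + ("1", "2", "4", "3")[idx]
        return "framework"

    def window(self, region: str) -> tuple:
        return {"1": self.cdr1, "2": self.cdr2,
                "3": self.cdr3, "4": self.de_loop}[region[1]]


class AntibodyComplex:
    """An annotated antibody(-antigen) structure.

    ``chain_roles`` maps chain id to one of ``heavy``, ``light``,
    ``antigen``.  ``cdr_labels`` is bookkeeping metadata (current
    cluster / length per CDR) maintained by the grafting and protocol
    layers; it travels with the structure so that label-aware energy
    hooks and recovery metrics can read it.
    """

    def __init__(self, chains: dict, chain_roles: dict,
                 light_chain_type: str = "kappa",
                 boundary_table: RegionBoundaryTable | None = None):
        if light_chain_type not in ("kappa", "lambda", "none"):
            raise FormatError(f"bad light_chain_type {light_chain_type!r}")
        self.chains = chains
        self.chain_roles = dict(chain_roles)
        self.light_chain_type = light_chain_type
        self.boundary_table = boundary_table or RegionBoundaryTable()
        self.cdr_labels: dict = {}

    # -- chain access ------------------------------------------------
    @property
    def antibody_chain_ids(self):
        return [c for c, r in self.chain_roles.items()
                if r in ("heavy", "light") and c in self.chains]

    @property
    def antigen_chain_ids(self):
        return [c for c, r in self.chain_roles.items()
                if r == "antigen" and c in self.chains]

    def chain(self, chain_id: str):
        return self.chains[chain_id]

    def residues(self, chain_ids=None):
        ids = chain_ids if chain_ids is not None else list(self.chains)
        for cid in ids:
            yield from self.chains[cid]

    def region_residues(self, region: str):
        out = []
        for cid in self.antibody_chain_ids:
            out.extend(r for r in self.chains[cid] if r.region == region)
        return out

    def region_chain(self, region: str) -> str:
        """Chain id hosting a CDR region label like ``L1`` or ``H3``."""
        role = "heavy" if region.startswith("H") else "light"
        for cid, r in self.chain_roles.items():
            if r == role and cid in self.chains:
                return cid
        raise AnnotationError(f"no {role} chain for region {region}")

    @property
    def region_map(self) -> dict:
        return {(res.chain_id, res.number_label): res.region
                for res in self.residues()}

    def copy(self) -> "AntibodyComplex":
        dup = AntibodyComplex(
            {cid: [r.copy() for r in residues]
             for cid, residues in self.chains.items()},
            self.chain_roles, self.light_chain_type, self.boundary_table)
        dup.cdr_labels = dict(self.cdr_labels)
        return dup

    def without_antigen(self) -> "AntibodyComplex":
        dup = self.copy()
        for cid in list(dup.chains):
            if dup.chain_roles.get(cid) == "antigen":
                del dup.chains[cid]
        return dup


def read_pdb(text: str, chain_roles: dict,
             boundary_table: RegionBoundaryTable | None = None,
             light_chain_type: str = "kappa") -> AntibodyComplex:
    """Parse PDB-format text into an annotated :class:`AntibodyComplex`.

    ``chain_roles`` maps chain id to heavy/light/antigen; chains absent
    from the mapping are treated as antigen.  Residues keep file order;
    missing carbonyl O atoms are rebuilt from ideal geometry.
    """
    try:
        structure = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"unparseable PDB text: {exc}") from exc
    if len(structure) == 0 or len(structure[0]) == 0:
        raise FormatError("no chains found in PDB text")
    model = structure[0]
    chains: dict = {}
    for chain in model:
        residues = []
        for pos, res in enumerate(chain, start=1):
            if res.name not in AA_3TO1:
                continue  # waters, ligands
            atoms = {}
            for atom in res:
                atoms[atom.name] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z])
            residues.append(Residue(
                chain_id=chain.name, seq_position=pos,
                number=res.seqid.num, icode=res.seqid.icode.strip(),
                aa=AA_3TO1[res.name], atoms=atoms))
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise FormatError("no amino-acid residues found")
    for residues in chains.values():
        _rebuild_missing_oxygens(residues)
        _flag_chain_breaks(residues)
    roles = {cid: chain_roles.get(cid, "antigen") for cid in chains}
    complex_ = AntibodyComplex(chains, roles, light_chain_type,
                               boundary_table)
    return annotate_regions(complex_, complex_.boundary_table)


def _rebuild_missing_oxygens(residues) -> None:
    for i, res in enumerate(residues):
        if "O" in res.atoms or not res.has_backbone():
            continue
        if i + 1 < len(residues) and "N" in residues[i + 1].atoms:
            psi = geometry.dihedral(res.atoms["N"], res.atoms["CA"],
                                    res.atoms["C"], residues[i + 1].atoms["N"])
        else:
            psi = 140.0  # terminal residue: ideal-ish placement
        res.atoms["O"] = geometry.place_atom(
            res.atoms["N"], res.atoms["CA"], res.atoms["C"],
            geometry.BOND_C_O, geometry.ANGLE_CA_C_O, psi + 180.0)


def _flag_chain_breaks(residues) -> None:
    for prev, res in zip(residues, residues[1:]):
        if "CA" in prev.atoms and "CA" in res.atoms:
            d = float(np.linalg.norm(res.atoms["CA"] - prev.atoms["CA"]))
            res.chain_break = d >= CHAIN_BREAK_CA_CA
        else:
            res.chain_break = True


def annotate_regions(complex_: AntibodyComplex,
                     boundary_table: RegionBoundaryTable | None = None,
                     require_regions=()) -> AntibodyComplex:
    """Label every residue with its region (CDRs, DE loops, framework).

    Antibody residues get exactly one label from the boundary-table
    windows; antigen residues are labeled ``antigen``.  Regions listed
    in ``require_regions`` must be non-empty.
    """
    table = boundary_table or complex_.boundary_table
    for cid, residues in complex_.chains.items():
        role = complex_.chain_roles.get(cid, "antigen")
        for res in residues:
            res.region = table.region_for(res.number, role)
    for region in require_regions:
        if not complex_.region_residues(region):
            raise AnnotationError(f"declared CDR window {region} is empty")
    for region in LOOP_REGIONS:
        residues = complex_.region_residues(region)
        if residues and not _contiguous(residues):
            raise AnnotationError(f"region {region} is not contiguous")
    return complex_


def _contiguous(residues) -> bool:
    positions = [r.seq_position for r in residues]
    chains = {r.chain_id for r in residues}
    return len(chains) == 1 and positions == list(
        range(positions[0], positions[0] + len(positions)))


def write_pdb(complex_: AntibodyComplex) -> str:
    """Serialize a complex to standard PDB ATOM/TER/END records."""
    if not any(True for _ in complex_.residues()):
        raise FormatError("cannot write an empty complex")
    structure = gemmi.Structure()
    structure.name = "cdrdesign"
    model = gemmi.Model("1")
    for cid, residues in complex_.chains.items():
        chain = gemmi.Chain(cid)
        for res in residues:
            if not res.has_backbone():
                raise FormatError(
                    f"residue {cid}/{res.number_label} missing backbone atoms")
            gres = gemmi.Residue()
            gres.name = AA_1TO3[res.aa]
            gres.het_flag = "A"
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(_element_of(name))
                atom.pos = gemmi.Position(*np.round(np.asarray(xyz, float), 3))
                atom.occ = 1.0
                atom.b_iso = 0.0
                gres.add_atom(atom)
            chain.add_residue(gres)
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    for entity in structure.entities:
        # single residues would otherwise serialize as HETATM
        entity.entity_type = gemmi.EntityType.Polymer
        entity.polymer_type = gemmi.PolymerType.PeptideL
    buf = io.StringIO()
    buf.write(structure.make_pdb_string())
    return buf.getvalue()


def _element_of(atom_name: str) -> str:
    if atom_name.startswith(("N",)):
        return "N"
    if atom_name.startswith(("O",)):
        return "O"
    if atom_name.startswith(("S",)):
        return "S"
    return "C"


def backbone_dihedrals(residues, region: str | None = None) -> list:
    """Per-residue (phi, psi, omega) in degrees for a residue stretch.

    ``residues`` is a full chain (list of :class:`Residue`).  When
    ``region`` is given, angles are returned only for residues with that
    region label, but flanking residues from the chain are used so the
    first phi / last psi are defined.  Undefined terminal angles are
    ``nan`` -- never fabricated.  A chain break inside the requested
    stretch raises :class:`DihedralError`.
    """
    residues = list(residues)
    if region is not None:
        idx = [i for i, r in enumerate(residues) if r.region == region]
        if not idx:
            raise DihedralError(f"no residues labeled {region}")
    else:
        idx = list(range(len(residues)))
    for i in idx[1:]:
        if residues[i].chain_break:
            raise DihedralError(
                f"chain break at {residues[i].chain_id}/"
                f"{residues[i].number_label}")
    out = []
    for i in idx:
        res = residues[i]
        prev_res = residues[i - 1] if i > 0 and not res.chain_break else None
        next_res = (residues[i + 1]
                    if i + 1 < len(residues) and not residues[i + 1].chain_break
                    else None)
        if not res.has_backbone():
            raise DihedralError(
                f"residue {res.chain_id}/{res.number_label} missing backbone")
        n, ca, c = res.atoms["N"], res.atoms["CA"], res.atoms["C"]
        phi = psi = omega = float("nan")
        if prev_res is not None and "C" in prev_res.atoms:
            phi = geometry.dihedral(prev_res.atoms["C"], n, ca, c)
            if "CA" in prev_res.atoms:
                omega = geometry.dihedral(prev_res.atoms["CA"],
                                          prev_res.atoms["C"], n, ca)
        if next_res is not None and "N" in next_res.atoms:
            psi = geometry.dihedral(n, ca, c, next_res.atoms["N"])
        out.append((phi, psi, omega))
    return out
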