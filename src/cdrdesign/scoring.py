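"""Energy models, interface energy, buried surface and interface residues.

The package's protocol code depends only on the :class:`EnergyModel`
contract: ``score(complex, chain_ids=None) -> float`` (lower is
better), deterministic for fixed coordinates, and additive over chain
subsets once they are out of interaction range.  The built-in
:class:`ReferenceEnergy` is a deliberately coarse potential -- a
soft-sphere clash penalty, a distance-capped contact well between
side-chain centroids, a backbone N...O hydrogen-bond proxy, and
per-type reference offsets.  It is NOT a replacement for a full
molecular mechanics or statistical potential; any model honoring the
contract can be plugged into the protocol.

All pair terms vanish beyond ``PAIR_CUTOFF`` (8 A), which makes the
additivity-at-separation contract exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

import biotite.structure as bst

from .errors import InterfaceError, ScoringError
from .sidechain import CENTROID_PARAMS

PAIR_CUTOFF = 8.0
CONTACT_FULL = 5.5          # contact well saturates below this distance
HBOND_CENTER = 2.9
HBOND_SIGMA = 0.3
HBOND_CUTOFF = 4.0
CLASH_SCALE = 0.89          # fraction of summed radii where clash begins
MIN_SEQ_SEP = 2             # pair terms ignore bonded / adjacent residues

#: heavy-atom radii by atom-name prefix (Angstrom)
ATOM_RADII = {"N": 1.55, "O": 1.52, "C": 1.70, "S": 1.80}

SASA_PROBE = 1.4
SASA_POINTS = 960


def atom_radius(atom_name: str, aa: str) -> float:
    if atom_name == "CEN":
        return CENTROID_PARAMS[aa][1]
    return ATOM_RADII.get(atom_name[0], 1.70)


@dataclass
class EnergyBreakdown:
    clash: float = 0.0
    contact: float = 0.0
    hbond_proxy: float = 0.0
    reference: float = 0.0
    dG_interface: float | None = None

    @property
    def total(self) -> float:
        return self.clash + self.contact + self.hbond_proxy + self.reference


class EnergyModel:
    """Contract: deterministic scalar score, lower is better."""

    def score(self, complex_, chain_ids=None) -> float:  # pragma: no cover
        raise NotImplementedError


class ConstantEnergy(EnergyModel):
    """A flat landscape; useful for sampling-bookkeeping studies."""

    def __init__(self, value: float = 0.0):
        self.value = float(value)

    def score(self, complex_, chain_ids=None) -> float:
        return self.value


@dataclass
class AtomTable:
    """Flat atom arrays extracted from a complex for pair scoring."""

    positions: np.ndarray       # (n, 3)
    radii: np.ndarray           # (n,)
    res_index: np.ndarray       # (n,) global residue ordinal
    chain_index: np.ndarray     # (n,)
    is_bb_n: np.ndarray         # (n,) bool
    is_bb_o: np.ndarray
    is_center: np.ndarray       # CEN (or CB/CA stand-in) flags
    aa: list = field(default_factory=list)          # per residue
    atom_names: list = field(default_factory=list)  # per atom

    @classmethod
    def from_complex(cls, complex_, chain_ids=None) -> "AtomTable":
        ids = list(chain_ids) if chain_ids is not None else list(complex_.chains)
        pos, rad, resi, chi = [], [], [], []
        bbn, bbo, cen, names = [], [], [], []
        aa_per_res = []
        res_counter = -1
        for c_idx, cid in enumerate(ids):
            for res in complex_.chains[cid]:
                res_counter += 1
                aa_per_res.append(res.aa)
                center_name = ("CEN" if "CEN" in res.atoms
                               else "CB" if "CB" in res.atoms else "CA")
                for name, xyz in res.atoms.items():
                    pos.append(xyz)
                    rad.append(atom_radius(name, res.aa))
                    resi.append(res_counter)
                    chi.append(c_idx)
                    bbn.append(name == "N")
                    bbo.append(name == "O")
                    cen.append(name == center_name)
                    names.append(name)
        if not pos:
            raise ScoringError("no atoms to score")
        return cls(np.array(pos, float), np.array(rad), np.array(resi),
                   np.array(chi), np.array(bbn), np.array(bbo),
                   np.array(cen), aa_per_res, names)


def _interacting_pairs(table: AtomTable):
    tree = cKDTree(table.positions)
    pairs = tree.query_pairs(PAIR_CUTOFF, output_type="ndarray")
    if len(pairs) == 0:
        return pairs
    i, j = pairs[:, 0], pairs[:, 1]
    same_chain = table.chain_index[i] == table.chain_index[j]
    seq_sep = np.abs(table.res_index[i] - table.res_index[j])
    keep = ~(same_chain & (seq_sep < MIN_SEQ_SEP))
    return pairs[keep]


def _pair_energies(table: AtomTable, weights: dict, with_grad: bool = False):
    pairs = _interacting_pairs(table)
    breakdown = EnergyBreakdown()
    grad = np.zeros_like(table.positions) if with_grad else None
    if len(pairs) == 0:
        return breakdown, grad
    i, j = pairs[:, 0], pairs[:, 1]
    delta = table.positions[i] - table.positions[j]
    dist = np.linalg.norm(delta, axis=1)
    dist = np.maximum(dist, 1e-6)
    unit = delta / dist[:, None]

    def accumulate(mask, dE_dd):
        if grad is None:
            return
        contrib = dE_dd[:, None] * unit[mask]
        np.add.at(grad, i[mask], contrib)
        np.add.at(grad, j[mask], -contrib)

    # soft-sphere clash
    rsum = CLASH_SCALE * (table.radii[i] + table.radii[j])
    m = dist < rsum
    if m.any():
        t = (rsum[m] - dist[m]) / rsum[m]
        breakdown.clash = float(weights["clash"] * np.sum(t ** 2))
        accumulate(m, weights["clash"] * 2.0 * t * (-1.0 / rsum[m]))

    # contact well between interaction centers
    m = table.is_center[i] & table.is_center[j] & (dist < PAIR_CUTOFF)
    if m.any():
        t = np.clip((dist[m] - CONTACT_FULL) / (PAIR_CUTOFF - CONTACT_FULL),
                    0.0, 1.0)
        s = 1.0 - (3.0 * t ** 2 - 2.0 * t ** 3)
        breakdown.contact = float(-weights["contact"] * np.sum(s))
        ds_dt = -(6.0 * t - 6.0 * t ** 2)
        inside = (dist[m] > CONTACT_FULL) & (dist[m] < PAIR_CUTOFF)
        dE = np.zeros_like(s)
        dE[inside] = (-weights["contact"] * ds_dt[inside]
                      / (PAIR_CUTOFF - CONTACT_FULL))
        accumulate(m, dE)

    # backbone N...O hydrogen-bond proxy
    m = (((table.is_bb_n[i] & table.is_bb_o[j])
          | (table.is_bb_o[i] & table.is_bb_n[j]))
         & (dist < HBOND_CUTOFF))
    if m.any():
        z = (dist[m] - HBOND_CENTER) / HBOND_SIGMA
        g = np.exp(-z ** 2)
        breakdown.hbond_proxy = float(-weights["hbond"] * np.sum(g))
        accumulate(m, weights["hbond"] * 2.0 * z / HBOND_SIGMA * g)

    return breakdown, grad


@dataclass
class ReferenceEnergy(EnergyModel):
    """Built-in coarse score: clash + contact + H-bond proxy + reference.

    ``reference_offsets`` maps residue type to a constant added once per
    residue (default: all zero).  Weights are in arbitrary reference
    units; the protocol's kT is expressed in the same units.
    """

    clash_weight: float = 10.0
    contact_weight: float = 0.5
    hbond_weight: float = 1.0
    reference_offsets: dict = field(default_factory=dict)

    @property
    def weights(self) -> dict:
        return {"clash": self.clash_weight, "contact": self.contact_weight,
                "hbond": self.hbond_weight}

    def breakdown(self, complex_, chain_ids=None) -> EnergyBreakdown:
        table = AtomTable.from_complex(complex_, chain_ids)
        bd, _ = _pair_energies(table, self.weights)
        bd.reference = float(sum(self.reference_offsets.get(aa, 0.0)
                                 for aa in table.aa))
        return bd

    def score(self, complex_, chain_ids=None) -> float:
        return self.breakdown(complex_, chain_ids).total

    def energy_and_grad(self, table: AtomTable):
        """Cartesian energy and gradient for restrained minimization."""
        bd, grad = _pair_energies(table, self.weights, with_grad=True)
        total = bd.total + sum(self.reference_offsets.get(aa, 0.0)
                               for aa in table.aa)
        return total, grad


class ResidueEnvironment:
    """Fixed surroundings of one residue for incremental packing.

    All pair terms of the reference energy are capped at 8 A and
    decompose over atom pairs, so while one residue's side chain is
    being optimized the rest of the system contributes a constant; the
    argmin over candidate types/states can therefore be taken on the
    residue-vs-environment terms alone.  This is exact, not an
    approximation.
    """

    def __init__(self, model: ReferenceEnergy, complex_, key):
        self.model = model
        pos, rad, resi, chi = [], [], [], []
        bbn, bbo, cen = [], [], []
        ordinal = -1
        self.res_ordinal = None
        self.chain_index = None
        for c_idx, cid in enumerate(complex_.chains):
            for res in complex_.chains[cid]:
                ordinal += 1
                if (res.chain_id, res.number_label) == key:
                    self.res_ordinal = ordinal
                    self.chain_index = c_idx
                    self.residue = res
                    continue
                center_name = ("CEN" if "CEN" in res.atoms
                               else "CB" if "CB" in res.atoms else "CA")
                for name, xyz in res.atoms.items():
                    pos.append(xyz)
                    rad.append(atom_radius(name, res.aa))
                    resi.append(ordinal)
                    chi.append(c_idx)
                    bbn.append(name == "N")
                    bbo.append(name == "O")
                    cen.append(name == center_name)
        if self.res_ordinal is None:
            raise ScoringError(f"residue {key} not found")
        self.positions = np.array(pos, float)
        self.radii = np.array(rad)
        self.res_index = np.array(resi)
        self.chain_index_arr = np.array(chi)
        self.is_bb_n = np.array(bbn)
        self.is_bb_o = np.array(bbo)
        self.is_center = np.array(cen)
        self.tree = cKDTree(self.positions)

    def score(self) -> float:
        """Residue-vs-environment energy for the residue's current state."""
        res = self.residue
        w = self.model.weights
        center_name = ("CEN" if "CEN" in res.atoms
                       else "CB" if "CB" in res.atoms else "CA")
        total = self.model.reference_offsets.get(res.aa, 0.0)
        for name, xyz in res.atoms.items():
            idx = np.array(self.tree.query_ball_point(xyz, PAIR_CUTOFF),
                           dtype=int)
            if len(idx) == 0:
                continue
            same_chain = self.chain_index_arr[idx] == self.chain_index
            seq_sep = np.abs(self.res_index[idx] - self.res_ordinal)
            keep = ~(same_chain & (seq_sep < MIN_SEQ_SEP))
            idx = idx[keep]
            if len(idx) == 0:
                continue
            dist = np.linalg.norm(self.positions[idx] - xyz, axis=1)
            dist = np.maximum(dist, 1e-6)
            rsum = CLASH_SCALE * (atom_radius(name, res.aa)
                                  + self.radii[idx])
            m = dist < rsum
            if m.any():
                t = (rsum[m] - dist[m]) / rsum[m]
                total += w["clash"] * float(np.sum(t ** 2))
            if name == center_name:
                m = self.is_center[idx]
                if m.any():
                    t = np.clip((dist[m] - CONTACT_FULL)
                                / (PAIR_CUTOFF - CONTACT_FULL), 0.0, 1.0)
                    total -= w["contact"] * float(
                        np.sum(1.0 - (3.0 * t ** 2 - 2.0 * t ** 3)))
            if name in ("N", "O"):
                m = ((self.is_bb_o[idx] if name == "N"
                      else self.is_bb_n[idx]) & (dist < HBOND_CUTOFF))
                if m.any():
                    z = (dist[m] - HBOND_CENTER) / HBOND_SIGMA
                    total -= w["hbond"] * float(np.sum(np.exp(-z ** 2)))
        return total


def reference_score(complex_, params: ReferenceEnergy | None = None,
                    chain_ids=None) -> EnergyBreakdown:
    """Score a complex with the built-in coarse reference potential."""
    model = params or ReferenceEnergy()
    for res in complex_.residues(chain_ids):
        if not res.has_backbone():
            raise ScoringError(
                f"residue {res.chain_id}/{res.number_label} missing "
                "backbone coordinates")
    return model.breakdown(complex_, chain_ids)


def interface_energy(complex_, energy: EnergyModel, repack=None) -> float:
    """dG = E(complex) - [E(antibody alone) + E(antigen alone)].

    The separated states are scored as disjoint chain subsets (exact
    separation under the additivity contract).  When a ``repack``
    callback is given it re-optimizes the side chains of each separated
    part (called as ``repack(complex, chain_ids) -> complex``).
    """
    ab = complex_.antibody_chain_ids
    ag = complex_.antigen_chain_ids
    if not ab or not ag:
        raise InterfaceError(
            "interface energy needs both antibody and antigen chains")
    e_complex = energy.score(complex_)
    ab_state, ag_state = complex_, complex_
    if repack is not None:
        ab_state = repack(complex_, ab)
        ag_state = repack(complex_, ag)
    return float(e_complex - energy.score(ab_state, ab)
                 - energy.score(ag_state, ag))


def buried_surface_area(complex_, probe_radius: float = SASA_PROBE,
                        point_number: int = SASA_POINTS) -> float:
    """SASA(antibody) + SASA(antigen) - SASA(complex), Shrake-Rupley.

    Quadrature uses ``point_number`` sphere points per atom (default
    960).  Heavy atoms only; radii from the package radii table.
    """
    ab = complex_.antibody_chain_ids
    ag = complex_.antigen_chain_ids
    if not ab or not ag:
        raise InterfaceError("buried surface needs antibody and antigen")
    total = _sasa(complex_, ab + ag, probe_radius, point_number)
    return float(_sasa(complex_, ab, probe_radius, point_number)
                 + _sasa(complex_, ag, probe_radius, point_number) - total)


def _sasa(complex_, chain_ids, probe_radius, point_number) -> float:
    table = AtomTable.from_complex(complex_, chain_ids)
    n = len(table.positions)
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(table.positions, np.float32)
    arr.set_annotation("chain_id", np.array(
        [str(c) for c in table.chain_index], dtype="U4"))
    arr.set_annotation("res_id", table.res_index + 1)
    arr.set_annotation("atom_name", np.array(table.atom_names, dtype="U6"))
    arr.set_annotation("element", np.array(
        [name[0] for name in table.atom_names], dtype="U2"))
    values = bst.sasa(arr, probe_radius=probe_radius,
                      point_number=point_number,
                      vdw_radii=np.asarray(table.radii, np.float32))
    return float(np.nansum(values))


def interface_residues(complex_, distance: float = 8.0) -> set:
    """Antibody/antigen residue pairs with any heavy-atom pair <= distance.

    Returns a set of ``((ab_chain, ab_label), (ag_chain, ag_label))``
    tuples.
    """
    ab_atoms, ab_keys = _atoms_with_keys(complex_, complex_.antibody_chain_ids)
    ag_atoms, ag_keys = _atoms_with_keys(complex_, complex_.antigen_chain_ids)
    if not len(ab_atoms) or not len(ag_atoms):
        return set()
    tree = cKDTree(ag_atoms)
    pairs = set()
    hits = tree.query_ball_point(ab_atoms, distance)
    for ab_idx, ag_hits in enumerate(hits):
        for ag_idx in ag_hits:
            pairs.add((ab_keys[ab_idx], ag_keys[ag_idx]))
    return pairs


def _atoms_with_keys(complex_, chain_ids):
    coords, keys = [], []
    for cid in chain_ids:
        for res in complex_.chains.get(cid, []):
            key = (cid, res.number_label)
            for xyz in res.atoms.values():
                coords.append(xyz)
                keys.append(key)
    return np.array(coords) if coords else np.empty((0, 3)), keys
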