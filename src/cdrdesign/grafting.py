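"""CDR grafting: overhang superposition, CCD closure, fallback minimizer.

Replacing a CDR backbone with a database conformation proceeds in three
stages.  (1) The entry's three flanking residues on each side are
least-squares superposed onto the corresponding framework anchors and
the native CDR residues are swapped for the entry's.  (2) If the
peptide junctions are not already closed, the insert is re-attached
exactly on the N side (rebuilt from the framework anchor with the
entry's internal torsions and ideal bond geometry) and cyclic
coordinate descent closes the C-side junction by rotating the phi/psi
of the movable residues: two framework residues and the first CDR
residue at each end.  (3) If CCD fails, a dihedral-restrained
minimization over the whole insert (both junctions movable) is tried.

A junction is closed when the peptide C-N distance is under 1.5 A and
the CA-C-N / C-N-CA angles lie within 15 degrees of the ideal
min/max windows (114.5-119.5 and 120-126 degrees respectively).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .errors import GraftError
from .model import annotate_regions, _flag_chain_breaks
from .sidechain import build_reduced_sidechain

# closure criteria
CN_DISTANCE_MAX = 1.5
CA_C_N_IDEAL = (114.5, 119.5)
C_N_CA_IDEAL = (120.0, 126.0)
ANGLE_TOLERANCE = 15.0

DEFAULT_OVERHANG = 3
DEFAULT_MAX_CYCLES = 100
PERTURB_SIGMA_DEG = 3.0
CCD_PASSES_PER_CYCLE = 2
#: Gauss-Newton stop: ghost mismatch comfortably inside the closure window
GN_CLOSE_TOL = 5e-3
CCD_OBJECTIVE_TOL = 1e-10


@dataclass
class JunctionGeometry:
    cn_distance: float
    ca_c_n_angle: float
    c_n_ca_angle: float

    def closed(self) -> bool:
        return (self.cn_distance < CN_DISTANCE_MAX
                and CA_C_N_IDEAL[0] - ANGLE_TOLERANCE <= self.ca_c_n_angle
                <= CA_C_N_IDEAL[1] + ANGLE_TOLERANCE
                and C_N_CA_IDEAL[0] - ANGLE_TOLERANCE <= self.c_n_ca_angle
                <= C_N_CA_IDEAL[1] + ANGLE_TOLERANCE)


@dataclass
class ClosureGeometry:
    n_terminal: JunctionGeometry
    c_terminal: JunctionGeometry


@dataclass
class GraftResult:
    complex: object
    closed: bool
    used_fallback: bool
    junction_geometry: ClosureGeometry | None
    internal_rmsd: float
    cycles: int = 0
    anchor_rmsd: float = 0.0


def check_closure(geom: ClosureGeometry) -> bool:
    """True iff both junctions satisfy the distance and angle windows."""
    return geom.n_terminal.closed() and geom.c_terminal.closed()


def measure_junction(prev_res, next_res) -> JunctionGeometry:
    c = prev_res.atoms["C"]
    ca_prev = prev_res.atoms["CA"]
    n = next_res.atoms["N"]
    ca_next = next_res.atoms["CA"]
    return JunctionGeometry(
        cn_distance=float(np.linalg.norm(c - n)),
        ca_c_n_angle=geometry.bond_angle(ca_prev, c, n),
        c_n_ca_angle=geometry.bond_angle(c, n, ca_next))


def measure_closure(complex_, target_cdr: str) -> ClosureGeometry:
    chain, i0, length = _cdr_span(complex_, target_cdr)
    residues = complex_.chains[chain]
    return ClosureGeometry(
        n_terminal=measure_junction(residues[i0 - 1], residues[i0]),
        c_terminal=measure_junction(residues[i0 + length - 1],
                                    residues[i0 + length]))


def _cdr_span(complex_, region: str):
    chain = complex_.region_chain(region)
    residues = complex_.chains[chain]
    idx = [i for i, r in enumerate(residues) if r.region == region]
    if not idx:
        raise GraftError(f"no residues labeled {region}")
    return chain, idx[0], len(idx)


def _cdr_labels(window: tuple, length: int):
    """Numbering labels for a grafted CDR of arbitrary length."""
    lo, hi = window
    capacity = hi - lo + 1
    labels = []
    for k in range(length):
        if k < capacity:
            labels.append((lo + k, ""))
        else:
            labels.append((hi, chr(ord("A") + k - capacity)))
    return labels


def place_by_overhang_superposition(entry, complex_, target_cdr: str,
                                    overhang: int = DEFAULT_OVERHANG):
    """Superpose the entry on its framework anchors and swap the CDR in.

    The 2 x ``overhang`` flank residues (backbone N/CA/C) define the
    rigid-body fit; flanks are then discarded and the native CDR
    residues are replaced by the entry's.  Junctions are left as open
    cutpoints for :func:`ccd_close`.  Returns a new complex.
    """
    if entry.flank < overhang:
        raise GraftError(
            f"entry {entry.source_pdb}/{entry.cdr} carries only "
            f"{entry.flank} flank residues; overhang={overhang}")
    chain, i0, old_len = _cdr_span(complex_, target_cdr)
    residues = complex_.chains[chain]
    if i0 < overhang or i0 + old_len + overhang > len(residues):
        raise GraftError(
            f"not enough framework around {target_cdr} for overhang "
            f"{overhang}")
    fl = entry.flank
    mobile = np.vstack([
        entry.coords[fl - overhang:fl, :3].reshape(-1, 3),
        entry.coords[fl + entry.length:fl + entry.length + overhang,
                     :3].reshape(-1, 3)])
    target = np.vstack(
        [residues[i].backbone()[:3] for i in range(i0 - overhang, i0)]
        + [residues[i].backbone()[:3]
           for i in range(i0 + old_len, i0 + old_len + overhang)])
    rot, trans, anchor_rmsd = geometry.kabsch(mobile, target)

    from .model import Residue  # local import to avoid cycle at module load
    window = complex_.boundary_table.window(target_cdr)
    labels = _cdr_labels(window, entry.length)
    new_residues = []
    for k in range(entry.length):
        coords = geometry.apply_transform(
            entry.coords[fl + k], rot, trans)
        num, icode = labels[k]
        res = Residue(chain_id=chain, seq_position=0, number=num,
                      icode=icode, aa=entry.sequence[k],
                      atoms={"N": coords[0], "CA": coords[1],
                             "C": coords[2], "O": coords[3]},
                      region=target_cdr)
        build_reduced_sidechain(res)
        new_residues.append(res)

    # only the grafted chain changes; other chains are shared read-only
    # (all coordinate updates in the package assign fresh objects)
    from .model import AntibodyComplex
    new_chain = ([r.copy() for r in residues[:i0]] + new_residues
                 + [r.copy() for r in residues[i0 + old_len:]])
    chains = {cid: (new_chain if cid == chain else complex_.chains[cid])
              for cid in complex_.chains}
    out = AntibodyComplex(chains, complex_.chain_roles,
                          complex_.light_chain_type, complex_.boundary_table)
    out.cdr_labels = dict(complex_.cdr_labels)
    for pos, res in enumerate(out.chains[chain], start=1):
        res.seq_position = pos
    _flag_chain_breaks(out.chains[chain])
    annotate_regions(out, out.boundary_table)
    out.cdr_labels[target_cdr] = {"cluster": entry.cluster_id,
                                  "length": entry.length,
                                  "source_pdb": entry.source_pdb}
    out._last_anchor_rmsd = anchor_rmsd
    return out


# ----------------------------------------------------------------------
# CCD closure


class TorsionChain:
    """A stretch of residues rebuilt from torsions toward a fixed anchor.

    The stretch is anchored on the N side at seed atoms (N/CA/C of the
    residue preceding it, plus that residue's psi); coordinates are
    regenerated from (phi, psi, omega) rows with ideal bond geometry.
    The free C-terminal end carries a "ghost" continuation whose match
    to the fixed anchor N/CA defines the closure objective.
    """

    def __init__(self, seed_n, seed_ca, seed_c, seed_psi, torsions,
                 anchor_n, anchor_ca):
        self.seed = (np.asarray(seed_n, float), np.asarray(seed_ca, float),
                     np.asarray(seed_c, float))
        self.seed_psi = float(seed_psi)
        self.torsions = np.array(torsions, float)
        self.anchor_n = np.asarray(anchor_n, float).copy()
        self.anchor_ca = np.asarray(anchor_ca, float).copy()
        self.coords = self._rebuild()
        self.ghosts = self._ghosts_from_coords()

    def _rebuild(self) -> np.ndarray:
        return geometry.extend_backbone(*self.seed, self.seed_psi,
                                        self.torsions)

    def ccd_pass(self, pairs) -> float:
        """One CCD sweep over (row, kind) torsions; returns the objective."""
        for local, kind in pairs:
            delta = self.optimal_delta(local, kind)
            self.rotate_torsion(local, kind, delta)
        return self.objective()

    def _axis(self, local: int, kind: int):
        res = self.coords[local]
        return (res[0], res[1]) if kind == 0 else (res[1], res[2])

    def gauss_newton(self, pairs, max_iter: int = 60, tol: float = 1e-16,
                     restraint_weight: float = 0.0,
                     reference=None, stop=None) -> float:
        """Damped Gauss-Newton on the closure objective over torsions.

        The ghost-junction positions are differentiable in each torsion
        (derivative of a rotation about the bond axis), so the normal
        equations are assembled analytically.  With
        ``restraint_weight`` > 0 the residual vector is augmented with
        harmonic deviations (radians) from ``reference`` torsion
        values, giving the dihedral-restrained fallback minimizer.
        """
        targets = np.array([self.anchor_n, self.anchor_ca])
        sqw = np.sqrt(restraint_weight) if restraint_weight > 0 else 0.0

        def full_objective():
            obj = self.objective()
            if sqw > 0:
                dev = np.radians([
                    geometry.angular_difference(self.torsions[i, k], ref)
                    for (i, k), ref in zip(pairs, reference)])
                obj += restraint_weight * float(np.sum(dev ** 2))
            return obj

        obj = full_objective()
        for _ in range(max_iter):
            if obj < tol or (stop is not None and stop()):
                break
            ghosts = self.ghost_junction()
            n_rows = 6 + (len(pairs) if sqw > 0 else 0)
            J = np.zeros((n_rows, len(pairs)))
            for col, (local, kind) in enumerate(pairs):
                a, b = self._axis(local, kind)
                u = geometry.normalize(b - a)
                # d(ghost)/d(torsion, rad) for a rotation about the axis
                rel = ghosts - a
                J[0:3, col] = geometry.cross3(u, rel[0])
                J[3:6, col] = geometry.cross3(u, rel[1])
            r = np.zeros(n_rows)
            r[:6] = (ghosts - targets).ravel()
            if sqw > 0:
                for row, ((i, k), ref) in enumerate(zip(pairs, reference)):
                    dev = np.radians(geometry.wrap_angle(
                        self.torsions[i, k] - ref))
                    r[6 + row] = sqw * dev
                    J[6 + row, row] = sqw
            delta, *_ = np.linalg.lstsq(J, -r, rcond=None)
            # cap the step so a near-singular Jacobian cannot fling the
            # torsions; the line search handles the rest
            norm = float(np.max(np.abs(delta)))
            if norm > 1.0:   # radians
                delta = delta / norm
            step = 1.0
            improved = False
            for _ in range(6):
                for (local, kind), d in zip(pairs, delta):
                    self.rotate_torsion(local, kind,
                                        float(np.degrees(d * step)))
                new = full_objective()
                if new < obj:
                    obj = new
                    improved = True
                    break
                for (local, kind), d in zip(pairs, delta):
                    self.rotate_torsion(local, kind,
                                        float(-np.degrees(d * step)))
                step *= 0.5
            if not improved:
                break
        return obj

    def _ghosts_from_coords(self) -> np.ndarray:
        last = self.coords[-1]
        psi = self.torsions[-1, 1]
        ghost_n = geometry.place_atom(last[0], last[1], last[2],
                                      geometry.BOND_C_N,
                                      geometry.ANGLE_CA_C_N, psi)
        ghost_ca = geometry.place_atom(last[1], last[2], ghost_n,
                                       geometry.BOND_N_CA,
                                       geometry.ANGLE_C_N_CA, 180.0)
        return np.array([ghost_n, ghost_ca])

    def ghost_junction(self) -> np.ndarray:
        """Predicted N/CA of residue f+1 continuing from the last CDR.

        Maintained incrementally: the ghost atoms ride rigidly on the
        chain under every torsion rotation.
        """
        return self.ghosts

    def objective(self) -> float:
        ghosts = self.ghost_junction()
        targets = np.array([self.anchor_n, self.anchor_ca])
        return float(np.sum((ghosts - targets) ** 2))

    def rotate_torsion(self, local: int, kind: int, delta_deg: float) -> None:
        """Rotate phi (kind 0) or psi (kind 1) of row ``local`` by +delta."""
        res = self.coords[local]
        if kind == 0:
            axis_a, axis_b = res[0], res[1]       # N -> CA
            same = (2, 3)                          # C, O move
        else:
            axis_a, axis_b = res[1], res[2]       # CA -> C
            same = (3,)                            # O moves
        # a positive rotation about the bond axis advances the torsion
        # (rotation matrix built inline; this is the hottest kernel)
        ux, uy, uz = axis_b[0] - axis_a[0], axis_b[1] - axis_a[1], \
            axis_b[2] - axis_a[2]
        inv = 1.0 / math.sqrt(ux * ux + uy * uy + uz * uz)
        ux *= inv
        uy *= inv
        uz *= inv
        theta = math.radians(delta_deg)
        c, s = math.cos(theta), math.sin(theta)
        t = 1.0 - c
        rot = np.array([
            [c + ux * ux * t, ux * uy * t - uz * s, ux * uz * t + uy * s],
            [uy * ux * t + uz * s, c + uy * uy * t, uy * uz * t - ux * s],
            [uz * ux * t - uy * s, uz * uy * t + ux * s, c + uz * uz * t]])
        trans = axis_a - rot @ axis_a
        rot_t = rot.T
        for a in same:
            self.coords[local, a] = rot @ self.coords[local, a] + trans
        if local + 1 < len(self.coords):
            block = self.coords[local + 1:].reshape(-1, 3)
            self.coords[local + 1:] = (block @ rot_t + trans).reshape(
                self.coords[local + 1:].shape)
        self.ghosts = self.ghosts @ rot_t + trans
        self.torsions[local, kind] = geometry.wrap_angle(
            self.torsions[local, kind] + delta_deg)

    def optimal_delta(self, local: int, kind: int) -> float:
        res = self.coords[local]
        axis_a, axis_b = (res[0], res[1]) if kind == 0 else (res[1], res[2])
        ghosts = self.ghost_junction()
        targets = np.array([self.anchor_n, self.anchor_ca])
        theta = geometry.ccd_optimal_angle(axis_a, axis_b, ghosts, targets)
        return float(np.degrees(theta))

    def junction_geometry(self) -> JunctionGeometry:
        last = self.coords[-1]
        return JunctionGeometry(
            cn_distance=float(np.linalg.norm(last[2] - self.anchor_n)),
            ca_c_n_angle=geometry.bond_angle(last[1], last[2], self.anchor_n),
            c_n_ca_angle=geometry.bond_angle(last[2], self.anchor_n,
                                             self.anchor_ca))

class _RebuildRegion(TorsionChain):
    """Torsion-space view of [f-2, f-1, CDR...] bound to a complex.

    The stretch is seeded at residue f-3 of the host chain; the anchor
    is the N/CA of the first framework residue after the CDR.
    """

    def __init__(self, complex_, target_cdr: str, insert_torsions=None):
        chain, i0, length = _cdr_span(complex_, target_cdr)
        self.complex = complex_
        self.chain = chain
        self.i0 = i0
        self.length = length
        residues = complex_.chains[chain]
        if i0 < 3 or i0 + length >= len(residues):
            raise GraftError(
                "need three framework residues before and one after the CDR")
        seed_res = residues[i0 - 3]
        seed_psi = geometry.dihedral(
            seed_res.atoms["N"], seed_res.atoms["CA"],
            seed_res.atoms["C"], residues[i0 - 2].atoms["N"])
        self.local_residues = residues[i0 - 2:i0 + length]  # f-2, f-1, CDR
        torsions = self._initial_torsions(residues, insert_torsions)
        super().__init__(seed_res.atoms["N"], seed_res.atoms["CA"],
                         seed_res.atoms["C"], seed_psi, torsions,
                         residues[i0 + length].atoms["N"],
                         residues[i0 + length].atoms["CA"])

    def _initial_torsions(self, residues, insert_torsions):
        rows = []
        for j, res in enumerate(self.local_residues):
            i = self.i0 - 2 + j
            prev = residues[i - 1]
            phi = geometry.dihedral(prev.atoms["C"], res.atoms["N"],
                                    res.atoms["CA"], res.atoms["C"])
            omega = geometry.dihedral(prev.atoms["CA"], prev.atoms["C"],
                                      res.atoms["N"], res.atoms["CA"])
            if i + 1 < len(residues):
                psi = geometry.dihedral(res.atoms["N"], res.atoms["CA"],
                                        res.atoms["C"],
                                        residues[i + 1].atoms["N"])
            else:
                psi = 140.0
            rows.append([phi, psi, omega])
        rows = np.array(rows, float)
        if insert_torsions is not None:
            insert = np.asarray(insert_torsions, float)
            if len(insert) != self.length:
                raise GraftError("insert torsion count != CDR length")
            rows[2:, :] = insert
        # the torsion crossing the open N-side cutpoint is meaningless
        # when measured; the rebuilt peptide bond is trans
        rows[2, 2] = 180.0
        return rows

    @property
    def movable(self):
        """(local index, torsion kind) pairs: f-2, f-1, CDR1, CDR_last."""
        last = 2 + self.length - 1
        pairs = [(0, 0), (0, 1), (1, 0), (1, 1), (2, 0), (2, 1)]
        if last > 2:
            pairs += [(last, 0), (last, 1)]
        return pairs

    def write_back(self) -> None:
        for res, coords in zip(self.local_residues, self.coords):
            res.atoms["N"] = coords[0].copy()
            res.atoms["CA"] = coords[1].copy()
            res.atoms["C"] = coords[2].copy()
            res.atoms["O"] = coords[3].copy()
            sg = res.atoms.get("SG")
            build_reduced_sidechain(res)
            if sg is not None:
                res.atoms["SG"] = sg
        _flag_chain_breaks(self.complex.chains[self.chain])


def ccd_close(complex_, target_cdr: str, insert_torsions=None,
              max_cycles: int = DEFAULT_MAX_CYCLES,
              perturb_sigma: float = PERTURB_SIGMA_DEG,
              rng: np.random.Generator | None = None,
              objective_trace: list | None = None,
              in_place: bool = False) -> GraftResult:
    """Close the grafted CDR's junctions by cyclic coordinate descent.

    Returns immediately (zero cycles) when the junctions already pass
    :func:`check_closure`.  Otherwise each attempt perturbs the movable
    phi/psi with Gaussian noise (sigma 3 deg), applies closed-form CCD
    rotations until the junction objective stalls, and stops as soon as
    the closure criteria pass.  A small BFGS polish of the movable
    torsions on the closure objective follows each failed attempt.
    Never raises on failure: returns ``closed=False``.
    """
    rng = rng or np.random.default_rng(0)
    geom = measure_closure(complex_, target_cdr)
    if check_closure(geom):
        return GraftResult(complex=complex_, closed=True, used_fallback=False,
                           junction_geometry=geom, internal_rmsd=0.0,
                           cycles=0)
    work = complex_ if in_place else complex_.copy()
    region = _RebuildRegion(work, target_cdr, insert_torsions)
    closed = False
    cycles = 0
    for cycle in range(max_cycles):
        cycles = cycle + 1
        if cycle > 0 and perturb_sigma > 0:
            for local, kind in region.movable:
                region.rotate_torsion(local, kind,
                                      float(rng.normal(0.0, perturb_sigma)))
        prev_obj = region.objective()
        for _ in range(CCD_PASSES_PER_CYCLE):
            for local, kind in region.movable:
                delta = region.optimal_delta(local, kind)
                region.rotate_torsion(local, kind, delta)
                if objective_trace is not None:
                    objective_trace.append(region.objective())
            obj = region.objective()
            if prev_obj - obj < CCD_OBJECTIVE_TOL:
                break
            prev_obj = obj
        if region.junction_geometry().closed():
            closed = True
            break
        region.gauss_newton(region.movable, max_iter=8, tol=GN_CLOSE_TOL,
                            stop=lambda: region.junction_geometry().closed())
        if region.junction_geometry().closed():
            closed = True
            break
    region.write_back()
    geom = measure_closure(work, target_cdr)
    closed = check_closure(geom)
    return GraftResult(complex=work, closed=closed, used_fallback=False,
                       junction_geometry=geom, internal_rmsd=0.0,
                       cycles=cycles)


def _fallback_close(complex_, target_cdr: str, insert_torsions,
                    restraint_weight: float = 0.02) -> GraftResult:
    """Whole-insert dihedral-restrained minimization (both junctions mobile).

    All insert phi/psi plus the movable framework torsions are free;
    deviations from the database torsions are harmonically restrained
    (Gauss-Newton on the augmented residuals) so the CDR keeps its
    cluster conformation as far as closure allows.
    """
    work = complex_.copy()
    region = _RebuildRegion(work, target_cdr, insert_torsions)
    free = [(i, k) for i in range(len(region.coords)) for k in (0, 1)]
    ref = [region.torsions[i, k] for i, k in free]
    region.gauss_newton(free, max_iter=200,
                        restraint_weight=restraint_weight, reference=ref,
                        stop=lambda: region.junction_geometry().closed())
    if not region.junction_geometry().closed():
        # last resort: drop the restraints entirely
        region.gauss_newton(free, max_iter=200,
                            stop=lambda: region.junction_geometry().closed())
    region.write_back()
    geom = measure_closure(work, target_cdr)
    return GraftResult(complex=work, closed=check_closure(geom),
                       used_fallback=True, junction_geometry=geom,
                       internal_rmsd=0.0)


def internal_cdr_rmsd(complex_, target_cdr: str, entry) -> float:
    """Backbone RMSD of the non-anchor CDR residues to the database entry.

    The first and last CDR residues are anchors (their torsions are
    movable during closure); interior residues are compared after
    least-squares superposition.
    """
    chain, i0, length = _cdr_span(complex_, target_cdr)
    if length <= 2 or entry.length != length:
        return 0.0
    residues = complex_.chains[chain]
    got = np.vstack([residues[i0 + k].backbone()
                     for k in range(1, length - 1)])
    want = entry.cdr_coords()[1:length - 1].reshape(-1, 3)
    _, _, value = geometry.kabsch(got, want)
    return value


@dataclass
class GraftConfig:
    overhang: int = DEFAULT_OVERHANG
    max_cycles: int = DEFAULT_MAX_CYCLES
    perturb_sigma: float = PERTURB_SIGMA_DEG
    use_fallback: bool = True


def graft_cdr(entry, complex_, target_cdr: str,
              config: GraftConfig | None = None,
              rng: np.random.Generator | None = None) -> GraftResult:
    """Full graft: place -> CCD closure -> restrained-minimizer fallback.

    The result records whether closure succeeded, whether the fallback
    path was used, the junction geometry, and the internal RMSD of the
    grafted loop to the database conformation.  A graft that fails both
    paths is returned with ``closed=False`` -- never silently accepted.
    """
    config = config or GraftConfig()
    placed = place_by_overhang_superposition(entry, complex_, target_cdr,
                                             config.overhang)
    anchor_rmsd = getattr(placed, "_last_anchor_rmsd", 0.0)
    torsions = np.column_stack([
        np.asarray(entry.dihedrals.flat()).reshape(-1, 2),
        np.asarray(entry.dihedrals.omegas if entry.dihedrals.omegas
                   else [180.0] * entry.length)])
    result = ccd_close(placed, target_cdr, insert_torsions=torsions,
                       max_cycles=config.max_cycles,
                       perturb_sigma=config.perturb_sigma, rng=rng,
                       in_place=True)  # `placed` is a fresh copy
    if not result.closed and config.use_fallback:
        result = _fallback_close(placed, target_cdr, torsions)
    result.anchor_rmsd = anchor_rmsd
    result.internal_rmsd = internal_cdr_rmsd(result.complex, target_cdr,
                                             entry)
    return result
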