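"""Synthetic antibody benchmark generator.

Builds idealized-geometry antibody-like scaffolds (heavy + light chain
+ a short helical antigen), a toy CDR database with a configurable
cluster composition, and ground-truth native labels -- everything the
recovery metrics need for closed-loop testing.

Key property: all scaffolds of a chain type share one rigid framework
template, and every generated cluster centroid is a loop conformation
*fitted to span that framework's anchor geometry* (real canonical
clusters all span conserved framework anchors; unconstrained random
torsions would not).  Database entries are centroids plus small
Gaussian torsion noise, so grafting any entry onto any fixture
antibody is geometrically feasible and usually closes in a few CCD
cycles.

The generator also provides :class:`PlantedNativeBonus`, an energy
hook that rewards the ground-truth native cluster only while antigen
chains are present.  Paired with a constant base score it isolates the
risk-ratio statistics from all scoring detail: with a bonus the design
process should enrich the native cluster (DRR > 1), with bonus zero it
must not (null behavior).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import database as dbm
from . import geometry
from . import grafting
from .clusters import ClusterCentroid, DihedralVector
from .errors import SyntheticSpecError
from .model import (AntibodyComplex, RegionBoundaryTable, Residue,
                    annotate_regions, _flag_chain_breaks)
from .scoring import ConstantEnergy, EnergyModel
from .sidechain import build_reduced_sidechain

#: residue types used for random CDR sequences (no Cys/Pro so the
#: design-mask auto-disables stay under the generator's control)
SEQ_ALPHABET = "ADEFGHIKLMNQRSTVWY"

BETA = (-120.0, 135.0)
TURN_A = (-60.0, -30.0)
TURN_B = (-90.0, 0.0)

#: template (placeholder) CDR lengths per region
TEMPLATE_CDR_LENGTHS = {"1": 11, "2": 8, "3": 9}

DEFAULT_LENGTHS = {
    "L1": (10, 11), "L2": (8,), "L3": (9,),
    "H1": (13,), "H2": (9, 10), "H3": (12,),
}


def default_composition(cdrs=None, lengths: dict | None = None,
                        clusters_per_length: int = 2) -> dict:
    """Equal-share cluster composition over the default length menu."""
    lengths = lengths or DEFAULT_LENGTHS
    cdrs = cdrs or tuple(lengths)
    comp: dict = {}
    for cdr in cdrs:
        ids = [f"{cdr}-{ln}-{idx + 1}" for ln in lengths[cdr]
               for idx in range(clusters_per_length)]
        comp[cdr] = {cid: 1.0 / len(ids) for cid in ids}
    return comp


@dataclass
class SyntheticSpec:
    """Conditions of a synthetic benchmark.

    ``composition`` maps CDR -> {cluster_id: share}; shares must sum
    to 1 per CDR.  ``native_bonus`` is the interface reward (in kT
    units of the protocol) granted to the planted native cluster by
    :class:`PlantedNativeBonus`.
    """

    n_antibodies: int = 6
    composition: dict = field(default_factory=default_composition)
    entries_per_cdr: int = 40
    noise_deg: float = 4.0
    mutation_rate: float = 0.3
    native_bonus: float = 5.0
    lambda_fraction: float = 0.0
    plant_proline: bool = False
    plant_disulfide: bool = False
    seed: int = 0

    def __post_init__(self):
        for cdr, shares in self.composition.items():
            total = sum(shares.values())
            if abs(total - 1.0) > 1e-9:
                raise SyntheticSpecError(
                    f"composition for {cdr} sums to {total}, not 1")
            if any(s < 0 for s in shares.values()):
                raise SyntheticSpecError("negative composition share")


@dataclass
class SyntheticBenchmark:
    """Generator output: fixtures, toy database, ground truth."""

    spec: SyntheticSpec
    antibodies: dict                 # ab_id -> AntibodyComplex
    native_labels: dict              # ab_id -> {cdr: {"cluster", "length"}}
    entries: list                    # toy CdrEntry database
    centroids: list                  # ClusterCentroid per generated cluster
    light_chain_types: dict = field(default_factory=dict)

    def centroid_index(self) -> dict:
        return {c.cluster_id: c for c in self.centroids}

    def energy_hook(self, ab_id: str,
                    base: EnergyModel | None = None) -> "PlantedNativeBonus":
        return PlantedNativeBonus(self.native_labels[ab_id],
                                  self.spec.native_bonus, base)


class PlantedNativeBonus(EnergyModel):
    """Rewards the planted native cluster while antigen is present.

    score = base score - bonus per graft-designed CDR currently
    carrying its native cluster, applied only when the scored subset
    includes antigen chains.  With the default constant base this makes
    the native cluster the unique energy optimum at the interface and
    leaves the antigen-absent landscape flat.
    """

    def __init__(self, native_labels: dict, bonus: float,
                 base: EnergyModel | None = None):
        self.native_labels = {cdr: dict(lab)
                              for cdr, lab in native_labels.items()}
        self.bonus = float(bonus)
        self.base = base or ConstantEnergy()

    def score(self, complex_, chain_ids=None) -> float:
        e = self.base.score(complex_, chain_ids)
        ag = set(complex_.antigen_chain_ids)
        if chain_ids is not None:
            ag &= set(chain_ids)
        if not ag:
            return e
        for cdr, labels in complex_.cdr_labels.items():
            native = self.native_labels.get(cdr)
            if native and labels.get("cluster") == native.get("cluster"):
                e -= self.bonus
        return e


# ----------------------------------------------------------------------
# framework template


def _framework_rows(n: int, fold_first: bool) -> list:
    rows = []
    for k in range(n):
        if fold_first and k == 0:
            phi, psi = TURN_A
        elif fold_first and k == 1:
            phi, psi = TURN_B
        else:
            phi, psi = BETA
        rows.append([phi, psi, 180.0])
    return rows


def _placeholder_loop_rows(n: int) -> list:
    pattern = (TURN_A, TURN_B)
    return [[*pattern[k % 2], 180.0] for k in range(n)]


def _template_layout(table: RegionBoundaryTable):
    """(label, region_digit) per residue of the template chain."""
    layout = []

    def framework(labels):
        layout.extend((lab, None) for lab in labels)

    framework(range(21, 27))
    c1 = table.cdr1[0]
    layout.extend((c1 + k, "1") for k in range(TEMPLATE_CDR_LENGTHS["1"]))
    framework(range(41, 45))
    c2 = table.cdr2[0]
    layout.extend((c2 + k, "2") for k in range(TEMPLATE_CDR_LENGTHS["2"]))
    framework(range(70, 73))
    framework(range(82, 90))          # DE loop (fixed conformation)
    framework(range(95, 98))
    c3 = table.cdr3[0]
    layout.extend((c3 + k, "3") for k in range(TEMPLATE_CDR_LENGTHS["3"]))
    framework(range(139, 143))
    return layout


def build_template_chain(chain_id: str, role: str, seed: int,
                         table: RegionBoundaryTable | None = None) -> list:
    """One idealized antibody variable-domain chain (list of residues).

    Framework torsions are fixed (identical for every chain built with
    any seed) so all scaffolds share one anchor geometry; only the
    sequence is seed-dependent.
    """
    table = table or RegionBoundaryTable()
    layout = _template_layout(table)
    rows = []
    i = 0
    while i < len(layout):
        label, digit = layout[i]
        if digit is None:
            n = 1
            while (i + n < len(layout) and layout[i + n][1] is None
                   and layout[i + n][0] == label + n):
                n += 1
            fold = i > 0  # fold back after every loop/segment boundary
            rows.extend(_framework_rows(n, fold_first=fold))
            i += n
        else:
            n = 1
            while i + n < len(layout) and layout[i + n][1] == digit:
                n += 1
            rows.extend(_placeholder_loop_rows(n))
            i += n
    coords = geometry.build_backbone(np.array(rows))
    rng = np.random.default_rng(seed)
    residues = []
    for pos, ((label, digit), xyz) in enumerate(zip(layout, coords), start=1):
        res = Residue(chain_id=chain_id, seq_position=pos, number=label,
                      icode="", aa=SEQ_ALPHABET[int(rng.integers(
                          len(SEQ_ALPHABET)))],
                      atoms={"N": xyz[0].copy(), "CA": xyz[1].copy(),
                             "C": xyz[2].copy(), "O": xyz[3].copy()},
                      region=table.region_for(label, role))
        build_reduced_sidechain(res)
        residues.append(res)
    _flag_chain_breaks(residues)
    return residues


def _transform_residues(residues, rotation, translation):
    for res in residues:
        for name, xyz in res.atoms.items():
            res.atoms[name] = rotation @ xyz + translation


def build_antigen_chain(chain_id: str, near: np.ndarray,
                        direction: np.ndarray, n_res: int = 10,
                        seed: int = 7) -> list:
    """A short ideal helix placed so its head sits ``near`` + 4.5 A."""
    rows = np.array([[-57.0, -47.0, 180.0]] * n_res)
    coords = geometry.build_backbone(rows)
    head = coords[0, 1]
    shift = (near + 4.5 * direction) - head
    rng = np.random.default_rng(seed)
    residues = []
    for pos in range(n_res):
        xyz = coords[pos] + shift
        res = Residue(chain_id=chain_id, seq_position=pos + 1,
                      number=pos + 1, icode="",
                      aa=SEQ_ALPHABET[int(rng.integers(len(SEQ_ALPHABET)))],
                      atoms={"N": xyz[0].copy(), "CA": xyz[1].copy(),
                             "C": xyz[2].copy(), "O": xyz[3].copy()})
        build_reduced_sidechain(res)
        residues.append(res)
    _flag_chain_breaks(residues)
    return residues


def build_scaffold(light_chain_type: str = "kappa", seed: int = 0,
                   with_antigen: bool = True) -> AntibodyComplex:
    """A full fixture complex: heavy + light chain and optional antigen."""
    heavy = build_template_chain("H", "heavy", seed * 7919 + 11)
    light = build_template_chain("L", "light", seed * 7919 + 12)
    rot, _ = geometry.rotation_about_axis(
        np.zeros(3), np.array([1.0, 0.0, 0.0]), np.pi)
    _transform_residues(light, rot, np.array([0.0, 24.0, 0.0]))
    chains = {"H": heavy, "L": light}
    roles = {"H": "heavy", "L": "light", "G": "antigen"}
    complex_ = AntibodyComplex(chains, roles, light_chain_type)
    annotate_regions(complex_)
    if with_antigen:
        h3 = complex_.region_residues("H3")
        tip = h3[len(h3) // 2].atoms["CA"]
        centroid = np.mean([r.atoms["CA"] for r in heavy], axis=0)
        direction = tip - centroid
        direction = direction / np.linalg.norm(direction)
        chains["G"] = build_antigen_chain("G", tip, direction)
        annotate_regions(complex_)
    return complex_


# ----------------------------------------------------------------------
# spanning-loop centroids


def fit_spanning_loop(template_chain, region: str, length: int,
                      rng: np.random.Generator, max_passes: int = 60,
                      restarts: int = 8, tol: float = 1e-8) -> np.ndarray:
    """Loop torsions of given length spanning the template's anchors.

    Starts from random loop-basin torsions, runs all-torsion CCD
    against the template's fixed C-side anchor until it stalls, then
    finishes with a Gauss-Newton refinement of the closure objective.
    Returns (length, 3) torsion rows (phi, psi, omega).
    """
    idx = [i for i, r in enumerate(template_chain) if r.region == region]
    if not idx:
        raise SyntheticSpecError(f"template has no region {region}")
    i0, tmpl_len = idx[0], len(idx)
    residues = template_chain
    seed_res = residues[i0 - 3]
    seed = (seed_res.atoms["N"], seed_res.atoms["CA"], seed_res.atoms["C"])
    seed_psi = geometry.dihedral(
        seed_res.atoms["N"], seed_res.atoms["CA"], seed_res.atoms["C"],
        residues[i0 - 2].atoms["N"])
    pre_rows = []
    for i in (i0 - 2, i0 - 1):
        res, prev = residues[i], residues[i - 1]
        pre_rows.append([
            geometry.dihedral(prev.atoms["C"], res.atoms["N"],
                              res.atoms["CA"], res.atoms["C"]),
            geometry.dihedral(res.atoms["N"], res.atoms["CA"],
                              res.atoms["C"], residues[i + 1].atoms["N"]),
            geometry.dihedral(prev.atoms["CA"], prev.atoms["C"],
                              res.atoms["N"], res.atoms["CA"])])
    anchor = residues[i0 + tmpl_len]
    anchor_n, anchor_ca = anchor.atoms["N"], anchor.atoms["CA"]

    def make_chain(loop_rows):
        return grafting.TorsionChain(
            *seed, seed_psi, np.vstack([pre_rows, loop_rows]),
            anchor_n, anchor_ca)

    def refine(chain):
        pairs = [(2 + k, t) for k in range(length) for t in (0, 1)]
        obj = chain.gauss_newton(pairs, max_iter=100)
        return chain.torsions[2:].copy(), obj

    for _ in range(restarts):
        loop_rows = np.column_stack([
            rng.uniform(-150.0, -45.0, size=length),
            rng.uniform(-60.0, 160.0, size=length),
            np.full(length, 180.0)])
        chain = make_chain(loop_rows)
        pairs = [(2 + k, t) for k in range(length) for t in (0, 1)]
        prev_obj = chain.objective()
        for _ in range(max_passes):
            obj = chain.ccd_pass(pairs)
            if obj < tol or prev_obj - obj < 1e-6:
                break
            prev_obj = obj
        if chain.objective() > 4.0:
            continue  # stuck far from the anchor; re-randomize
        rows, obj = refine(chain)
        if obj < tol and make_chain(rows).junction_geometry().closed():
            return _wrap_rows(rows)
    raise SyntheticSpecError(
        f"could not fit a spanning {region} loop of length {length}")


#: fitted centroid conformations are deterministic per (cluster, seed)
_FIT_CACHE: dict = {}


def _fit_cached(template_chain, region: str, length: int, cluster_id: str,
                seed: int) -> np.ndarray:
    import zlib

    key = (cluster_id, seed)
    if key not in _FIT_CACHE:
        rng = np.random.default_rng(np.random.SeedSequence(
            [seed, zlib.crc32(cluster_id.encode()) & 0x7FFFFFFF]))
        _FIT_CACHE[key] = fit_spanning_loop(template_chain, region, length,
                                            rng)
    return _FIT_CACHE[key]


# ----------------------------------------------------------------------
# benchmark assembly


def _entry_coords(template_chain, region: str, loop_rows: np.ndarray,
                  flank: int = 3) -> np.ndarray:
    """(L + 2*flank, 4, 3) backbone built from template flank + loop."""
    idx = [i for i, r in enumerate(template_chain) if r.region == region]
    i0, tmpl_len = idx[0], len(idx)
    residues = template_chain
    seed_res = residues[i0 - flank - 1]
    seed_psi = geometry.dihedral(
        seed_res.atoms["N"], seed_res.atoms["CA"], seed_res.atoms["C"],
        residues[i0 - flank].atoms["N"])
    rows = []
    for i in list(range(i0 - flank, i0)) + [None] \
            + list(range(i0 + tmpl_len, i0 + tmpl_len + flank)):
        if i is None:
            rows.extend(list(loop_rows))
            continue
        res, prev = residues[i], residues[i - 1]
        nxt = residues[i + 1]
        rows.append([
            geometry.dihedral(prev.atoms["C"], res.atoms["N"],
                              res.atoms["CA"], res.atoms["C"]),
            geometry.dihedral(res.atoms["N"], res.atoms["CA"],
                              res.atoms["C"], nxt.atoms["N"]),
            geometry.dihedral(prev.atoms["CA"], prev.atoms["C"],
                              res.atoms["N"], res.atoms["CA"])])
    rows = np.array(rows, float)
    # the torsions crossing from the loop into the C-flank are the
    # template's, which is what a real flank extraction would carry
    return geometry.extend_backbone(
        seed_res.atoms["N"], seed_res.atoms["CA"], seed_res.atoms["C"],
        seed_psi, rows)


def _wrap_rows(rows: np.ndarray) -> np.ndarray:
    out = rows.copy()
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            out[i, j] = geometry.wrap_angle(out[i, j])
    return out


def make_synthetic_benchmark(spec: SyntheticSpec,
                             rng: np.random.Generator | None = None
                             ) -> SyntheticBenchmark:
    """Generate fixture antibodies, a toy CDR database and ground truth.

    Cluster centroids are fitted per (CDR, length); database entries
    add Gaussian torsion noise (sigma ``spec.noise_deg``) and mutated
    cluster-consensus sequences.  Each antibody's native CDRs are
    planted by grafting a noiseless centroid conformation; the planted
    labels are returned as ground truth.
    """
    rng = rng or np.random.default_rng(spec.seed)
    templates = {"heavy": build_template_chain("H", "heavy", 11),
                 "light": build_template_chain("L", "light", 12)}

    # --- centroids ---------------------------------------------------
    centroids = []
    centroid_rows: dict = {}
    consensus: dict = {}
    for cdr, shares in spec.composition.items():
        template = templates["heavy" if cdr.startswith("H") else "light"]
        for cid in sorted(shares):
            length = int(cid.split("-")[1])
            rows = _fit_cached(template, cdr, length, cid, spec.seed)
            centroid_rows[cid] = rows
            centroids.append(ClusterCentroid(
                cluster_id=cid, cdr=cdr, length=length,
                gene="heavy" if cdr.startswith("H") else "kappa",
                centroid_dihedrals=DihedralVector.from_phi_psi(
                    rows[:, 0], rows[:, 1], rows[:, 2])))
            consensus[cid] = "".join(
                SEQ_ALPHABET[int(rng.integers(len(SEQ_ALPHABET)))]
                for _ in range(length))

    # --- database entries --------------------------------------------
    entries = []
    for cdr, shares in spec.composition.items():
        template = templates["heavy" if cdr.startswith("H") else "light"]
        ids = sorted(shares)
        counts = _allocate_counts([shares[c] for c in ids],
                                  spec.entries_per_cdr)
        serial = 0
        for cid, count in zip(ids, counts):
            length = int(cid.split("-")[1])
            for _ in range(count):
                serial += 1
                rows = centroid_rows[cid].copy()
                rows[:, :2] += rng.normal(0.0, spec.noise_deg,
                                          size=(length, 2))
                rows = _wrap_rows(rows)
                coords = _entry_coords(template, cdr, rows)
                seq = _mutate(consensus[cid], spec.mutation_rate, rng)
                gene = "heavy" if cdr.startswith("H") else (
                    "lambda" if rng.random() < spec.lambda_fraction
                    else "kappa")
                entries.append(dbm.CdrEntry(
                    source_pdb=f"syn{serial:04d}{cdr.lower()}", cdr=cdr,
                    length=length, cluster_id=cid, sequence=seq,
                    dihedrals=DihedralVector.from_phi_psi(
                        rows[:, 0], rows[:, 1], rows[:, 2]),
                    coords=coords, gene=gene, species="synthetic",
                    germline="IGSYN1",
                    resolution=float(np.round(rng.uniform(1.5, 2.5), 2)),
                    r_factor=float(np.round(rng.uniform(0.15, 0.25), 3)),
                    centroid_distance_norm=float(
                        np.round(rng.uniform(0.0, 1.0), 3))))

    # --- fixture antibodies ------------------------------------------
    antibodies: dict = {}
    native_labels: dict = {}
    light_types: dict = {}
    for a in range(spec.n_antibodies):
        ab_id = f"ab{a:03d}"
        light = ("lambda" if rng.random() < spec.lambda_fraction
                 else "kappa")
        scaffold = build_scaffold(light, seed=a)
        labels = {}
        for cdr, shares in spec.composition.items():
            ids = sorted(shares)
            probs = np.array([shares[c] for c in ids])
            cid = ids[int(rng.choice(len(ids), p=probs / probs.sum()))]
            length = int(cid.split("-")[1])
            rows = centroid_rows[cid]
            template = templates["heavy" if cdr.startswith("H") else "light"]
            entry = dbm.CdrEntry(
                source_pdb=f"native-{ab_id}", cdr=cdr, length=length,
                cluster_id=cid, sequence=consensus[cid],
                dihedrals=DihedralVector.from_phi_psi(
                    rows[:, 0], rows[:, 1], rows[:, 2]),
                coords=_entry_coords(template, cdr, rows),
                gene="heavy" if cdr.startswith("H") else light,
                species="synthetic", germline="IGSYN1")
            result = grafting.graft_cdr(entry, scaffold, cdr, rng=rng)
            if not result.closed:
                raise SyntheticSpecError(
                    f"failed to plant native {cdr} for {ab_id}")
            scaffold = result.complex
            labels[cdr] = {"cluster": cid, "length": length}
        if spec.plant_proline:
            _plant_proline(scaffold, "L1", position=4)
        if spec.plant_disulfide:
            _plant_disulfide(scaffold, "L1", positions=(2, 5))
        antibodies[ab_id] = scaffold
        native_labels[ab_id] = labels
        light_types[ab_id] = light
    return SyntheticBenchmark(spec=spec, antibodies=antibodies,
                              native_labels=native_labels, entries=entries,
                              centroids=centroids,
                              light_chain_types=light_types)


def _allocate_counts(shares, total: int) -> list:
    raw = np.array(shares, float) * total
    counts = np.maximum(np.round(raw).astype(int), 1)
    while counts.sum() > total:
        counts[int(np.argmax(counts))] -= 1
    while counts.sum() < total:
        counts[int(np.argmax(raw - counts))] += 1
    return counts.tolist()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for aa in seq:
        if rng.random() < rate:
            out.append(SEQ_ALPHABET[int(rng.integers(len(SEQ_ALPHABET)))])
        else:
            out.append(aa)
    return "".join(out)


def _plant_proline(complex_, region: str, position: int) -> None:
    residues = complex_.region_residues(region)
    res = residues[min(position, len(residues) - 1)]
    res.aa = "P"
    build_reduced_sidechain(res)


def _plant_disulfide(complex_, region: str, positions=(2, 5)) -> None:
    residues = complex_.region_residues(region)
    a = residues[min(positions[0], len(residues) - 1)]
    b = residues[min(positions[1], len(residues) - 1)]
    for res in (a, b):
        res.aa = "C"
        build_reduced_sidechain(res)
    cb_a, cb_b = a.atoms["CB"], b.atoms["CB"]
    delta = cb_b - cb_a
    a.atoms["SG"] = cb_a + 0.45 * delta
    b.atoms["SG"] = cb_b - 0.45 * delta
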