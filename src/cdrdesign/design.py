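"""Sequence-design palettes, design masks, packing shells and the packer.

Palettes say which residue types a position may adopt: either sampled
from a cluster sequence profile (repeated draws; every type drawn at
least once is allowed, the native always is) or a conservative set (all
types scoring >= 0 against the native in a BLOSUM matrix).  Masks say
which positions may change type at all: prolines, disulfide-bonded
cysteines and the H3 kink-determining stem (first 2 / last 3 residues
of H3) are never designable unless explicitly forced.

Packing is a greedy randomized sweep: shell residues are visited in
seeded random order; at each, every allowed type and discrete
side-chain state is evaluated under the energy model and the best is
committed.  This is a deliberate miniature of simulated-annealing
rotamer packing -- good enough for the coarse reduced representation,
and exhaustively checkable on tiny instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from Bio.Align import substitution_matrices

from .errors import DirectiveError, PaletteError
from .model import AMINO_ACIDS
from .scoring import ReferenceEnergy
from .sidechain import n_states, set_residue_type

DISULFIDE_SG_CUTOFF = 2.5
SHELL_DISTANCE = 6.0
H3_STEM_NTERM = 2
H3_STEM_CTERM = 3
DEFAULT_SWEEPS = 2

_MATRIX_CACHE: dict = {}


def _matrix(name: str):
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = substitution_matrices.load(name)
    return _MATRIX_CACHE[name]


def conservative_set(aa: str, matrix: str = "BLOSUM62") -> set:
    """Residue types scoring >= 0 against ``aa``; always contains ``aa``."""
    if aa not in AMINO_ACIDS:
        raise PaletteError(f"unknown amino-acid code {aa!r}")
    m = _matrix(matrix)
    return {b for b in AMINO_ACIDS if m[aa][b] >= 0} | {aa}


@dataclass
class DesignPalette:
    """Allowed amino-acid sets per designable position (CDR-ordered)."""

    allowed: list                 # list[set[str]], one per CDR position
    provenance: str = "profile"   # profile | conservative | native_only

    def __post_init__(self):
        self.allowed = [set(a) for a in self.allowed]


def profile_palette(profile, native_seq: str, rounds: int,
                    rng: np.random.Generator) -> DesignPalette:
    """Palette from repeated draws of a cluster sequence profile.

    Per position, ``rounds`` independent draws are taken from the
    profile distribution; every drawn type is allowed, and the native
    type always is.  Identical seeds give identical palettes.
    """
    if profile.length != len(native_seq):
        raise PaletteError(
            f"profile length {profile.length} != native CDR length "
            f"{len(native_seq)}")
    probs = profile.probs
    allowed = []
    for pos, native in enumerate(native_seq):
        draws = rng.choice(20, size=rounds, p=probs[pos])
        types = {AMINO_ACIDS[i] for i in np.unique(draws)}
        types.add(native)
        allowed.append(types)
    return DesignPalette(allowed, provenance="profile")


def conservative_palette(native_seq: str,
                         matrix: str = "BLOSUM62") -> DesignPalette:
    return DesignPalette([conservative_set(aa, matrix) for aa in native_seq],
                         provenance="conservative")


def native_palette(native_seq: str) -> DesignPalette:
    return DesignPalette([{aa} for aa in native_seq], provenance="native_only")


@dataclass
class DesignMask:
    """Per-residue design status plus optional per-position type limits."""

    status: dict = field(default_factory=dict)        # key -> design|repack_only|fixed
    auto_disabled: dict = field(default_factory=dict) # key -> reason
    allowed_types: dict = field(default_factory=dict) # key -> set[str]

    def of(self, key) -> str:
        return self.status.get(key, "repack_only")


def _residue_key(res):
    return (res.chain_id, res.number_label)


def find_disulfide_cysteines(complex_) -> set:
    """Keys of cysteines whose SG pairs with another SG under 2.5 A."""
    sg = [(res, res.atoms["SG"]) for res in complex_.residues()
          if res.aa == "C" and "SG" in res.atoms]
    out = set()
    for i, (ri, xi) in enumerate(sg):
        for rj, xj in sg[i + 1:]:
            if np.linalg.norm(xi - xj) < DISULFIDE_SG_CUTOFF:
                out.add(_residue_key(ri))
                out.add(_residue_key(rj))
    return out


def build_design_mask(complex_, designing, overrides=None,
                      force: bool = False) -> DesignMask:
    """Design mask over all residues of the complex.

    ``designing`` lists the CDR regions whose positions may change
    type.  Prolines, disulfide cysteines and the H3 stem are
    auto-disabled to repack-only; ``overrides`` (resfile-like text or
    directive list) can disable further positions or restrict types,
    but re-enabling an auto-disabled position requires ``force``.
    """
    mask = DesignMask()
    disulfides = find_disulfide_cysteines(complex_)
    for res in complex_.residues():
        mask.status[_residue_key(res)] = "repack_only"
    for region in designing:
        residues = complex_.region_residues(region)
        for pos, res in enumerate(residues):
            key = _residue_key(res)
            if res.aa == "P":
                mask.auto_disabled[key] = "proline"
            elif key in disulfides:
                mask.auto_disabled[key] = "disulfide"
            elif region == "H3" and (pos < H3_STEM_NTERM
                                     or pos >= len(residues) - H3_STEM_CTERM):
                mask.auto_disabled[key] = "h3_stem"
            else:
                mask.status[key] = "design"
    for key, reason in mask.auto_disabled.items():
        if not force:
            mask.status[key] = "repack_only"
        else:
            mask.status[key] = "design"
    _apply_overrides(mask, complex_, overrides, force)
    return mask


def _apply_overrides(mask, complex_, overrides, force) -> None:
    if overrides is None:
        return
    if isinstance(overrides, str):
        lines = overrides.splitlines()
    else:
        lines = list(overrides)
    known = {_residue_key(res) for res in complex_.residues()}
    for raw in lines:
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 3:
            raise DirectiveError(f"bad override line: {raw!r}")
        key = (parts[0], parts[1])
        if key not in known:
            raise DirectiveError(f"override references unknown residue {key}")
        op = parts[2].upper()
        if op == "FIX":
            mask.status[key] = "fixed"
        elif op == "REPACK":
            mask.status[key] = "repack_only"
        elif op == "ALLOW":
            if len(parts) < 4:
                raise DirectiveError(f"ALLOW needs a type list: {raw!r}")
            types = set(parts[3])
            bad = types - set(AMINO_ACIDS)
            if bad:
                raise DirectiveError(f"unknown types {bad} in: {raw!r}")
            mask.allowed_types[key] = types
            if key in mask.auto_disabled and not force:
                continue  # stays repack-only without the force flag
            mask.status[key] = "design"
        else:
            raise DirectiveError(f"unknown override op {op!r}")


def packing_shell(complex_, focus_cdr: str, neighbor_cdrs=(),
                  shell_distance: float = SHELL_DISTANCE) -> set:
    """Residue keys of the focus CDR, its neighbors and everything near.

    A residue joins the shell when any of its heavy atoms lies within
    ``shell_distance`` of any atom of the focus/neighbor regions
    (minimum heavy-atom distance, inclusive).  Recomputed on demand so
    it tracks the current coordinates.
    """
    core_keys = set()
    core_coords = []
    for region in (focus_cdr, *neighbor_cdrs):
        for res in complex_.region_residues(region):
            core_keys.add(_residue_key(res))
            core_coords.extend(res.atoms.values())
    if not core_coords:
        return core_keys
    tree = cKDTree(np.array(core_coords))
    shell = set(core_keys)
    for res in complex_.residues():
        key = _residue_key(res)
        if key in shell:
            continue
        coords = res.heavy_coords()
        dist, _ = tree.query(coords, k=1)
        if np.min(dist) <= shell_distance:
            shell.add(key)
    return shell


#: joint design spaces up to this many states are solved exactly
ENUMERATION_LIMIT = 512


def pack_and_design(complex_, palette: dict, mask: DesignMask, shell: set,
                    energy, rng: np.random.Generator,
                    sweeps: int = DEFAULT_SWEEPS):
    """Pack/design the shell; returns a new complex.

    ``palette`` maps residue key -> iterable of allowed types for
    positions under design (missing keys fall back to the native type).
    When the joint space of allowed (type, state) combinations is small
    (<= ``ENUMERATION_LIMIT``) the optimizer enumerates it exhaustively
    and commits the global optimum.  Otherwise shell residues are
    visited in seeded random order and each commit is the greedy
    energy-argmin over allowed types x discrete side-chain states, so
    the total energy is non-increasing across commits.
    """
    work = complex_.copy()
    index = {}
    for res in work.residues():
        index[_residue_key(res)] = res
    keys = [k for k in sorted(shell) if k in index
            and mask.of(k) != "fixed"]

    candidates = {}
    joint = 1
    for key in keys:
        res = index[key]
        if mask.of(key) == "design":
            types = sorted(set(palette.get(key, {res.aa})) | {res.aa})
            limit = mask.allowed_types.get(key)
            if limit:
                types = sorted((set(types) & limit) | {res.aa})
        else:
            types = [res.aa]
        cands = [(aa, state) for aa in types for state in range(n_states(aa))]
        candidates[key] = cands
        joint *= len(cands)
    if 1 < joint <= ENUMERATION_LIMIT:
        return _pack_exhaustive(work, index, keys, candidates, energy)

    for _ in range(max(1, int(sweeps))):
        order = rng.permutation(len(keys))
        for ordinal in order:
            key = keys[int(ordinal)]
            res = index[key]
            if mask.of(key) == "design":
                types = sorted(set(palette.get(key, {res.aa})))
                limit = mask.allowed_types.get(key)
                if limit:
                    types = sorted((set(types) & limit) | {res.aa})
                if res.aa not in types:
                    types.append(res.aa)
            else:
                types = [res.aa]
            incumbent = res.aa
            best = None
            # the reference energy is pairwise and distance-capped, so
            # candidates can be ranked on the residue-vs-environment
            # terms alone (exact, and ~100x cheaper than full rescores)
            env = None
            if isinstance(energy, ReferenceEnergy):
                from .scoring import ResidueEnvironment
                env = ResidueEnvironment(energy, work, key)
            for aa in types:
                for state in range(n_states(aa)):
                    set_residue_type(res, aa, state)
                    e = env.score() if env is not None else energy.score(work)
                    # ties keep the incumbent type, then alphabetical
                    cand = (e, 0 if aa == incumbent else 1,
                            AMINO_ACIDS.index(aa), state)
                    if best is None or cand < best:
                        best = cand
            aa = AMINO_ACIDS[best[2]]
            set_residue_type(res, aa, best[3])
    return work


def _pack_exhaustive(work, index, keys, candidates, energy):
    """Exact search over a small joint (type, state) space."""
    import itertools

    best = None
    for combo in itertools.product(*(candidates[k] for k in keys)):
        for key, (aa, state) in zip(keys, combo):
            set_residue_type(index[key], aa, state)
        e = energy.score(work)
        rank = (e, tuple(combo))
        if best is None or rank < best[0]:
            best = (rank, combo)
    for key, (aa, state) in zip(keys, best[1]):
        set_residue_type(index[key], aa, state)
    return work


def score_point_mutation(complex_, key, aa: str, energy) -> float:
    """Energy change of a single residue-type substitution (plumbing)."""
    work = complex_.copy()
    for res in work.residues():
        if _residue_key(res) == key:
            before = energy.score(work)
            set_residue_type(res, aa)
            return float(energy.score(work) - before)
    raise DirectiveError(f"unknown residue {key}")
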