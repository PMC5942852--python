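# Methods

This note documents the models, algorithms, defaults and deliberate
simplifications behind `cdrdesign`, in the order the pipeline uses
them.

## Structure model and region annotation

A complex is a set of chains of residues carrying backbone N/CA/C/O
coordinates, an aligned framework numbering label (integer plus
optional insertion code), and a region label. Chain roles
(heavy/light/antigen) come from an explicit configuration map — there
is no sequence-based chain typing and no renumbering engine; inputs
must already carry aligned numbering. CDRs are located by label
windows in a configurable `RegionBoundaryTable`. The shipped defaults
are AHo-style windows:

| region | labels |
|---|---|
| CDR1 (L1/H1) | 27–40 |
| CDR2 (L2/H2) | 58–68 |
| DE loop (L4/H4) | 82–89 |
| CDR3 (L3/H3) | 107–138 |

Only the DE-loop window is fixed by convention; the CDR windows are a
documented assumption and fully configurable. PDB I/O goes through
gemmi; missing carbonyl oxygens are rebuilt from ideal geometry.
Signed dihedrals follow the standard convention (verified against
Bio.PDB): invariant under traversal reversal, negated by mirror
reflection, range (−180°, 180°].

## Cluster metric, assignment, outliers, H3 kink

The distance between two CDR conformations of equal length is computed
on their (φ, ψ) pairs as the squared-chord form
d² = Σ 2(1 − cos Δθ), reported as a per-angle average mapped back to
degrees via arccos(1 − d²/2) — i.e. the angle whose chord equals the
RMS per-angle chord. A plain circular mean-absolute-difference form is
available as a switch. Assignment is nearest centroid among centroids
of matching CDR type and length, ties broken lexicographically.
A conformation farther than 40° (per-angle average) or 1.5 Å backbone
RMSD from every centroid is an outlier — strict inequalities, and the
rule is never applied to H3, which does not form tight clusters.
Omega/cis annotations in cluster names are matched as metadata; a
warning is emitted when measured ω disagrees with a `cisN` token.

The H3 base is classified *kinked* when the pseudo-dihedral of the
last three H3 CAs plus the following conserved residue's CA lies
within ±90° of zero (inclusive boundary; the threshold is
configurable).

## CDR database

One row per CDR conformation: coordinates including three flanking
residues per side, (φ, ψ, ω) torsions, sequence, cluster id, gene
(heavy/κ/λ), species, germline, resolution, R-factor, normalized
centroid distance, and an H3 kink flag (computed from coordinates at
ingest when absent). Quality control: inclusive resolution ≤ 2.8 Å and
R ≤ 0.30 cutoffs, then cluster-outlier removal. Redundancy is culled
on identical (CDR, sequence), keeping the entry with best resolution,
then lowest R, then lowest normalized centroid distance, then
lexicographic source id — "non-redundant" is not further specified
upstream, so the (CDR, sequence) key is a documented assumption.

Per-cluster sequence profiles use add-`pseudocount` smoothing
(default 1): p(aa | pos) = (count + 1)/(n + 20). A profile is usable
for design only when its cluster has at least 10 non-redundant
members; the CDRSet for grafting independently requires at least 5
unique same-gene sequences per cluster. These two thresholds are kept
separate on purpose. Storage is a flat TSV with JSON columns — no
database server needed, and a user export in the same schema drops in.

CDRSet queries honor include/exclude lists for lengths, clusters,
species, germlines and source structures, a kinked-only switch for H3,
and a gene restriction: light-chain CDRs are limited to the antibody's
own κ/λ class by default (framework–CDR compatibility), heavy CDRs to
heavy-gene entries.

## Grafting and closure

A graft superposes the donor's 2×3 flank backbone (N/CA/C) onto the
framework anchors by least-squares (Kabsch), swaps the CDR residues,
and renumbers them into the region window (insertion codes absorb
lengths beyond the window capacity). If the junctions do not already
satisfy the closure criteria, the insert is re-attached exactly on the
N side — rebuilt from the framework anchor with the donor's internal
torsions and ideal bond geometry — and the C-side junction is closed
by cyclic coordinate descent over the movable torsions: φ/ψ of two
framework residues and the first CDR residue at each end. Closed-form
CCD rotations are followed by a damped Gauss–Newton polish of the same
torsions on the closure objective (the ghost-continuation mismatch at
the anchor); the Jacobian of a rotation about a bond axis is analytic,
so no numeric differentiation is involved. Failed attempts perturb the
movable φ/ψ with Gaussian noise (σ = 3°, seeded) and retry, up to
`max_cycles` (default 100; the protocol escalates after 2).

The fallback for grafts CCD cannot close is a dihedral-restrained
minimization with *all* insert torsions free (harmonic restraints to
the donor torsions, Gauss–Newton on the augmented residuals), which
trades some internal-conformation fidelity for closure; its use is
recorded per graft so benchmark statistics can separate the paths.

A junction is closed when the peptide C–N distance is below 1.5 Å and
the CA–C–N and C–N–CA angles lie within 15° of the ideal ranges
114.5–119.5° and 120–126°. Both junctions must pass — a graft with one
open junction is not usable. Torsion-space moves necessarily transport
interior insert residues rigidly; the fixed-region guarantee is that
every residue outside the movable set and the insert is bit-identical
before and after closure. For CCD-closed grafts the interior of the
loop (excluding the two movable end residues, whose torsion changes
move the rest only rigidly) reproduces the donor conformation
essentially exactly.

## Sequence design and packing

Side chains use a reduced representation: an ideal Cβ plus one
per-type pseudo-centroid sphere placed along the Cα→Cβ direction, with
three discrete tilt states standing in for rotamers. No external
rotamer library is required, and the `EnergyModel` contract accepts
full-atom models if supplied.

Design palettes come from the current cluster's profile (a configured
number of seeded draws per position; every drawn type plus the native
is allowed) or, when the profile is unusable, from BLOSUM62
conservative sets ({b : score(a,b) ≥ 0}). Prolines,
disulfide-bonded cysteines (SG–SG < 2.5 Å) and the H3 kink-determining
stem (first 2, last 3 residues) are never designable unless explicitly
forced; resfile-like overrides (`<chain> <label> FIX|REPACK|ALLOW
<types>`) can restrict further.

The packing shell is the focus CDR, its declared neighbors, and every
residue with a heavy atom within 6 Å (inclusive), recomputed on demand
from the current coordinates. The packer solves joint design spaces of
up to 512 (type, state) combinations *exactly* by enumeration — a
two-residue design problem is below that bound, so toy instances are
provably optimal — and otherwise runs greedy randomized sweeps:
residues in seeded random order, committing the energy-argmin at each
visit (ties keep the incumbent type), so the energy is non-increasing
across commits. Pure coordinate descent is a heuristic on coupled
instances; the exact-below-a-bound design removes that caveat where it
can be removed cheaply. For the built-in reference energy, candidates
are ranked on the residue-vs-environment pair terms only — exact,
because all pair terms are distance-capped and decomposable.

## Scoring

The built-in `ReferenceEnergy` is a deliberately coarse potential, not
a substitute force field: (i) soft-sphere clash k·((R−d)/R)² below
R = 0.89·(rᵢ+rⱼ); (ii) a contact well between side-chain interaction
centers, −w·s(d) with s smooth-stepping from 1 below 5.5 Å to 0 at
8 Å; (iii) a backbone N···O hydrogen-bond proxy, a Gaussian well at
2.9 Å (σ 0.3 Å, cut at 4 Å); (iv) per-type reference offsets (zero by
default). All terms vanish beyond 8 Å, which makes additivity over
separated chain subsets exact — interface energy is computed as
E(complex) − E(antibody) − E(antigen) on disjoint subsets, with an
optional repack callback for the separated states. Analytic Cartesian
gradients support the restrained pre-minimization. Buried surface area
is Shrake–Rupley SASA (via biotite, probe 1.4 Å, 960 points/atom by
default); interface residues are antibody/antigen pairs with any
heavy-atom pair within 8 Å.

## Protocol

Defaults: 25 outer cycles, 1 inner cycle, kT = 1 in reference-energy
units (exposed in config), equal CDR weights, even-cluster graft
sampling, acceptance on total energy. The inner cycle runs
dock-perturbation (if enabled) → pack/design over the shell →
backbone minimization (`none` by default; `greedy_min` is restrained
torsion descent that preserves closure, `relax_lite` ramps the clash
weight with interleaved packing) → inner Metropolis; the best inner
state returns to the outer loop. The run's output is the lowest
acceptance-energy state observed. Unclosable grafts are rejected but
still counted as sampled. In antigen-absent mode the antigen chains
are removed and acceptance falls back to total energy (interface
energy is meaningless without a partner). All randomness derives from
the config seed through `numpy.random.SeedSequence`; identical inputs
give byte-identical score files.

## Synthetic benchmark generator

Fixture antibodies are idealized NeRF-built scaffolds: a fixed
framework template per chain type (identical geometry across all
scaffolds, seed-dependent sequences), CDR loops planted by grafting
noiseless cluster-centroid conformations, a light chain placed beside
the heavy chain, and a short helical antigen seated 4.5 Å off the H3
tip. Cluster centroids are *fitted to span the template's anchor
geometry* (all-torsion CCD plus Gauss–Newton from random loop-basin
starts) — real canonical clusters all span conserved framework
anchors, and unconstrained random torsions would not. Database entries
add Gaussian torsion noise (σ = 4°) and mutate a cluster-consensus
sequence at 30% per position (alphabet excludes Cys/Pro so the
design-mask rules stay under generator control; dedicated options
plant a proline or an SG-paired cysteine bridge for mask tests).

What the generator does *not* emulate: real side-chain packing,
solvation, crystallographic noise, correlated framework variation
between antibodies, and any physical preference among clusters.
Passing tests on these fixtures therefore validate geometry,
bookkeeping and statistics — not force-field-dependent recovery rates
on real structures.

`PlantedNativeBonus` is the energy hook for closed-loop statistics: a
flat base score minus a bonus per CDR currently carrying its
ground-truth native cluster, applied only when antigen chains are in
the scored subset. With bonus ≥ 5 kT the native cluster is the unique
optimum at the interface; with bonus 0 the landscape is exactly flat,
giving a clean null. Recovery studies use random-start grafting (the
native loop is replaced by a random database entry before cycle 1);
without it, a flat-landscape trajectory would trivially report its
native starting point as the best-observed state and bias the null.

## Study sizes

Benchmark studies are sized for a desk run on one CPU: the closure
census grafts 500 random (entry, antibody) pairs; the
sampling-bookkeeping study runs 60 fixture antibodies × 10 trajectories
× 100 outer cycles (one tenth of the full 100-trajectory scale, whose
expectation — 100,000 graft attempts per CDR across six CDRs — it
reproduces by a factor-of-ten extrapolation); the planted-native
recovery study uses 6 antibodies × 6 trajectories × 20 cycles per
condition. Larger sizes only tighten the same statistics.

## Known limitations

- The reference score has no electrostatics, solvation or orientation-
  dependent hydrogen bonding; its numbers are not comparable to any
  production energy function, and benchmark DRR/ARR magnitudes from
  such functions are out of scope by design.
- The fallback graft path can perturb the internal loop conformation
  by more than the CCD path's ~0 Å; consumers should check
  `used_fallback` when conformational fidelity matters.
- Insertion-code ordering follows file order; exotic numbering
  dialects with out-of-order insertions are not interpreted.
- `deterministic_graft` supports a single graft-design CDR, matching
  its purpose of exhaustively enumerating one CDR's options.
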