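"""CDR structure database: ingest, culling, profiles and CDRSet queries.

The database is a flat table of CDR conformations harvested from
experimental structures (one row per CDR), stored as TSV with JSON
columns for dihedrals and backbone coordinates.  Entries carry three
flanking residues on each side of the loop so grafting can superpose
overhang anchors.

Quality control mirrors standard curation practice: resolution and
R-factor cutoffs (inclusive, defaults 2.8 A / 0.30), removal of cluster
outliers (> 40 deg or > 1.5 A from the centroid, never applied to H3),
and redundancy culling by identical (cdr, sequence) keeping the entry
with best resolution, then R factor, then normalized centroid distance.

Per-cluster sequence profiles (position-specific amino-acid
probabilities with add-``pseudocount`` smoothing) drive profile-based
sequence design; a profile is usable only when its cluster has at
least ``PROFILE_MIN_MEMBERS`` non-redundant members.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import clusters as ct
from .errors import ConfigError, ProfileError, SchemaError
from .model import AMINO_ACIDS

RESOLUTION_CUTOFF = 2.8
R_FACTOR_CUTOFF = 0.30
#: clusters need this many unique sequences (same gene) to enter a CDRSet
CDRSET_MIN_CLUSTER_MEMBERS = 5
#: clusters need more members than this for profile-based design
PROFILE_MIN_MEMBERS = 10
FLANK = 3

DB_VERSION = "cdrdesign-db-1"


@dataclass
class CdrEntry:
    """One database CDR: conformation, cluster label and provenance."""

    source_pdb: str
    cdr: str
    length: int
    cluster_id: str
    sequence: str
    dihedrals: ct.DihedralVector
    coords: np.ndarray            # (length + 2*FLANK, 4, 3) N/CA/C/O
    gene: str                     # heavy | kappa | lambda
    species: str = "unknown"
    germline: str = "unknown"
    resolution: float = 2.0
    r_factor: float = 0.2
    centroid_distance_norm: float = 0.0
    kinked: bool | None = None    # H3 only
    flank: int = FLANK

    def __post_init__(self):
        if not (len(self.sequence) == self.length == self.dihedrals.length):
            raise SchemaError(
                f"{self.source_pdb}/{self.cdr}: sequence ({len(self.sequence)}), "
                f"length ({self.length}) and dihedrals "
                f"({self.dihedrals.length}) disagree")
        if self.resolution <= 0:
            raise SchemaError("resolution must be positive")
        self.coords = np.asarray(self.coords, float)
        if self.coords.shape != (self.length + 2 * self.flank, 4, 3):
            raise SchemaError(
                f"{self.source_pdb}/{self.cdr}: coords shape "
                f"{self.coords.shape} does not match length+2*flank")

    @property
    def key(self):
        return (self.cdr, self.sequence)

    def cdr_coords(self) -> np.ndarray:
        return self.coords[self.flank:self.flank + self.length]


@dataclass
class ClusterProfile:
    """Per-position amino-acid probabilities for one CDR cluster."""

    cluster_id: str
    n_sequences: int
    counts: np.ndarray            # (length, 20) raw counts
    pseudocount: float = 1.0
    min_members: int = PROFILE_MIN_MEMBERS

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def probs(self) -> np.ndarray:
        smoothed = self.counts + self.pseudocount
        return smoothed / smoothed.sum(axis=1, keepdims=True)

    @property
    def usable(self) -> bool:
        return self.n_sequences >= self.min_members

    def sample_position(self, position: int, rng: np.random.Generator) -> str:
        return AMINO_ACIDS[int(rng.choice(20, p=self.probs[position]))]


@dataclass
class CdrSetFilter:
    """User rules selecting which database CDRs may be grafted."""

    include_lengths: dict = field(default_factory=dict)   # cdr -> [lengths]
    exclude_lengths: dict = field(default_factory=dict)
    include_clusters: dict = field(default_factory=dict)  # cdr -> [ids]
    exclude_clusters: dict = field(default_factory=dict)
    include_species: list = field(default_factory=list)
    exclude_species: list = field(default_factory=list)
    include_germlines: list = field(default_factory=list)
    exclude_germlines: list = field(default_factory=list)
    exclude_source_pdbs: list = field(default_factory=list)
    gene_restriction: str = "auto"   # auto | heavy | kappa | lambda | any
    kink_only: bool = False          # H3 only
    min_cluster_members: int = CDRSET_MIN_CLUSTER_MEMBERS

    def __post_init__(self):
        for inc, exc, what in (
                (self.include_species, self.exclude_species, "species"),
                (self.include_germlines, self.exclude_germlines, "germlines")):
            overlap = set(inc) & set(exc)
            if overlap:
                raise ConfigError(
                    f"include and exclude {what} overlap: {sorted(overlap)}")
        for cdr in set(self.include_clusters) & set(self.exclude_clusters):
            overlap = (set(self.include_clusters[cdr])
                       & set(self.exclude_clusters[cdr]))
            if overlap:
                raise ConfigError(
                    f"include and exclude clusters overlap for {cdr}")


@dataclass
class CdrSet:
    """Filtered per-CDR entry lists available for graft design."""

    entries: dict = field(default_factory=dict)  # cdr -> [CdrEntry]

    def for_cdr(self, cdr: str):
        return self.entries.get(cdr, [])

    def clusters(self, cdr: str):
        out: dict = {}
        for e in self.for_cdr(cdr):
            out.setdefault(e.cluster_id, []).append(e)
        return out

    def lengths(self, cdr: str):
        out: dict = {}
        for e in self.for_cdr(cdr):
            out.setdefault(e.length, []).append(e)
        return out


# ----------------------------------------------------------------------
# ingest / culling


def ingest_entries(raw, resolution_cutoff: float = RESOLUTION_CUTOFF,
                   r_factor_cutoff: float = R_FACTOR_CUTOFF,
                   centroids=None) -> list:
    """Quality-filter raw entries: cutoffs, outliers, H3 kink labels.

    Cutoffs are inclusive (an entry at exactly 2.8 A / 0.30 survives).
    When ``centroids`` are supplied, entries whose dihedral distance to
    their matching centroid flags them as outliers are dropped (H3
    exempt).  H3 entries missing a kink label get one computed from
    their coordinates (the conserved residue following H3 is the first
    C-terminal flank residue).
    """
    entries = list(raw)
    for e in entries:
        if not isinstance(e, CdrEntry):
            raise SchemaError("ingest_entries expects CdrEntry rows")
    survivors = []
    centroid_index = {c.cluster_id: c for c in (centroids or [])}
    for e in entries:
        if e.resolution > resolution_cutoff or e.r_factor > r_factor_cutoff:
            continue
        if e.cdr != "H3" and e.cluster_id in centroid_index:
            cent = centroid_index[e.cluster_id]
            assignment = ct.ClusterAssignment(
                cluster_id=e.cluster_id,
                distance_deg=ct.dihedral_distance(
                    e.dihedrals, cent.centroid_dihedrals))
            if ct.flag_outlier(assignment, e.cdr):
                continue
        if e.cdr == "H3" and e.kinked is None:
            e = replace(e, kinked=_compute_kink(e))
        survivors.append(e)
    return survivors


def _compute_kink(entry: CdrEntry) -> bool:
    ca = entry.coords[:, 1]
    # last three H3 residues + the residue immediately after the loop
    last = entry.flank + entry.length
    four = ca[last - 3:last + 1]
    return ct.classify_h3_kink(four) == "kinked"


def cull_redundant(group) -> CdrEntry:
    """Single representative of entries sharing (cdr, sequence).

    Order: highest resolution (smallest A value), then lowest R factor,
    then lowest normalized centroid distance, then source pdb id.
    """
    group = list(group)
    if not group:
        raise SchemaError("cull_redundant on empty group")
    return min(group, key=lambda e: (e.resolution, e.r_factor,
                                     e.centroid_distance_norm, e.source_pdb))


def cull_all(entries) -> list:
    """Apply redundancy culling across a whole entry table."""
    groups: dict = {}
    for e in entries:
        groups.setdefault(e.key, []).append(e)
    return [cull_redundant(g) for g in groups.values()]


def build_profile(members, pseudocount: float = 1.0,
                  min_members: int = PROFILE_MIN_MEMBERS) -> ClusterProfile:
    """Position-specific amino-acid profile from cluster members.

    probs[pos][aa] = (count + pseudocount) / (n + 20 * pseudocount).
    """
    members = list(members)
    if not members:
        raise ProfileError("cannot build a profile from zero members")
    cluster_ids = {m.cluster_id for m in members}
    lengths = {m.length for m in members}
    if len(lengths) != 1 or len(cluster_ids) != 1:
        raise ProfileError(
            f"profile members must share cluster and length; got "
            f"{cluster_ids} / lengths {lengths}")
    length = lengths.pop()
    counts = np.zeros((length, 20))
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for m in members:
        for pos, aa in enumerate(m.sequence):
            counts[pos, aa_index[aa]] += 1
    return ClusterProfile(cluster_id=cluster_ids.pop(),
                          n_sequences=len(members), counts=counts,
                          pseudocount=pseudocount, min_members=min_members)


def build_profiles(entries, pseudocount: float = 1.0,
                   min_members: int = PROFILE_MIN_MEMBERS) -> dict:
    """Profiles for every cluster present in a (culled) entry table."""
    by_cluster: dict = {}
    for e in entries:
        by_cluster.setdefault(e.cluster_id, []).append(e)
    return {cid: build_profile(group, pseudocount, min_members)
            for cid, group in by_cluster.items()}


# ----------------------------------------------------------------------
# CDRSet query


def query_cdrset(entries, filter_: CdrSetFilter, designing,
                 light_chain_type: str = "kappa") -> CdrSet:
    """Build the per-CDR graftable sets honoring all filter rules.

    Light-chain CDRs are limited to entries from the antibody's own
    light-chain gene (kappa/lambda) unless the filter overrides the
    gene restriction.  An empty set for a CDR that is to be
    graft-designed is a configuration error.
    """
    out: dict = {}
    for cdr in designing:
        candidates = [e for e in entries if e.cdr == cdr]
        gene = _effective_gene(cdr, filter_.gene_restriction, light_chain_type)
        if gene is not None:
            candidates = [e for e in candidates if e.gene == gene]
        inc_len = filter_.include_lengths.get(cdr)
        if inc_len:
            candidates = [e for e in candidates if e.length in inc_len]
        exc_len = filter_.exclude_lengths.get(cdr, [])
        candidates = [e for e in candidates if e.length not in exc_len]
        inc_cl = filter_.include_clusters.get(cdr)
        if inc_cl:
            candidates = [e for e in candidates if e.cluster_id in inc_cl]
        exc_cl = filter_.exclude_clusters.get(cdr, [])
        candidates = [e for e in candidates if e.cluster_id not in exc_cl]
        if filter_.include_species:
            candidates = [e for e in candidates
                          if e.species in filter_.include_species]
        candidates = [e for e in candidates
                      if e.species not in filter_.exclude_species]
        if filter_.include_germlines:
            candidates = [e for e in candidates
                          if e.germline in filter_.include_germlines]
        candidates = [e for e in candidates
                      if e.germline not in filter_.exclude_germlines]
        candidates = [e for e in candidates
                      if e.source_pdb not in filter_.exclude_source_pdbs]
        if filter_.kink_only and cdr == "H3":
            candidates = [e for e in candidates if e.kinked]
        # cluster population threshold: unique sequences per cluster
        by_cluster: dict = {}
        for e in candidates:
            by_cluster.setdefault(e.cluster_id, set()).add(e.sequence)
        candidates = [e for e in candidates
                      if len(by_cluster[e.cluster_id])
                      >= filter_.min_cluster_members]
        if not candidates:
            raise ConfigError(
                f"CDRSet for {cdr} is empty under the current filter "
                f"(gene={gene}, min_cluster_members="
                f"{filter_.min_cluster_members})")
        out[cdr] = candidates
    return CdrSet(entries=out)


def _effective_gene(cdr: str, restriction: str, light_chain_type: str):
    if restriction == "any":
        return None
    if restriction in ("heavy", "kappa", "lambda"):
        return restriction
    # auto: heavy CDRs from heavy gene, light CDRs from the antibody's type
    if cdr.startswith("H"):
        return "heavy"
    if light_chain_type == "none":
        return None
    return light_chain_type


# ----------------------------------------------------------------------
# TSV serialization


def entries_to_frame(entries) -> pd.DataFrame:
    rows = []
    for e in entries:
        phi = [p for p, _ in e.dihedrals.angles]
        psi = [s for _, s in e.dihedrals.angles]
        rows.append({
            "source_pdb": e.source_pdb, "cdr": e.cdr, "length": e.length,
            "cluster_id": e.cluster_id, "sequence": e.sequence,
            "gene": e.gene, "species": e.species, "germline": e.germline,
            "resolution": e.resolution, "r_factor": e.r_factor,
            "centroid_distance_norm": e.centroid_distance_norm,
            "kinked": "" if e.kinked is None else str(bool(e.kinked)),
            "flank": e.flank,
            "phi": json.dumps(phi), "psi": json.dumps(psi),
            "omega": json.dumps(list(e.dihedrals.omegas)),
            "coords": json.dumps(np.round(e.coords, 4).tolist()),
        })
    return pd.DataFrame(rows)


def frame_to_entries(frame: pd.DataFrame) -> list:
    required = {"source_pdb", "cdr", "length", "cluster_id", "sequence",
                "gene", "resolution", "r_factor", "phi", "psi", "coords"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"database table missing columns: {sorted(missing)}")
    entries = []
    for _, row in frame.iterrows():
        phi = json.loads(row["phi"])
        psi = json.loads(row["psi"])
        omega = json.loads(row["omega"]) if "omega" in row else []
        kinked = row.get("kinked", "")
        entries.append(CdrEntry(
            source_pdb=str(row["source_pdb"]), cdr=str(row["cdr"]),
            length=int(row["length"]), cluster_id=str(row["cluster_id"]),
            sequence=str(row["sequence"]),
            dihedrals=ct.DihedralVector.from_phi_psi(phi, psi, omega),
            coords=np.array(json.loads(row["coords"])),
            gene=str(row["gene"]),
            species=str(row.get("species", "unknown")),
            germline=str(row.get("germline", "unknown")),
            resolution=float(row["resolution"]),
            r_factor=float(row["r_factor"]),
            centroid_distance_norm=float(
                row.get("centroid_distance_norm", 0.0)),
            kinked=None if kinked in ("", "nan", None) else kinked == "True",
            flank=int(row.get("flank", FLANK))))
    return entries


def save_database(entries, path) -> None:
    frame = entries_to_frame(entries)
    with open(path, "w") as fh:
        fh.write(f"# {DB_VERSION}\n")
        frame.to_csv(fh, sep="\t", index=False)


def load_database(path) -> list:
    frame = pd.read_csv(path, sep="\t", comment="#",
                        keep_default_na=False, dtype=str)
    return frame_to_entries(frame)


def centroids_to_frame(centroids) -> pd.DataFrame:
    rows = []
    for c in centroids:
        rows.append({
            "cluster_id": c.cluster_id, "cdr": c.cdr, "length": c.length,
            "gene": c.gene,
            "phi": json.dumps([p for p, _ in c.centroid_dihedrals.angles]),
            "psi": json.dumps([s for _, s in c.centroid_dihedrals.angles]),
            "omega": json.dumps(list(c.centroid_dihedrals.omegas)),
        })
    return pd.DataFrame(rows)


def frame_to_centroids(frame: pd.DataFrame) -> list:
    out = []
    for _, row in frame.iterrows():
        out.append(ct.ClusterCentroid(
            cluster_id=str(row["cluster_id"]), cdr=str(row["cdr"]),
            length=int(row["length"]), gene=str(row["gene"]),
            centroid_dihedrals=ct.DihedralVector.from_phi_psi(
                json.loads(row["phi"]), json.loads(row["psi"]),
                json.loads(row["omega"]) if "omega" in row else None)))
    return out
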