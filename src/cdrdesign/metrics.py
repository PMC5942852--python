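"""Design-recovery statistics: %Sampled, %Recovered, risk ratios, CIs.

Two risk ratios quantify design success.  The design risk ratio (DRR)
is the frequency of the native CDR feature (length or cluster) among
final decoys divided by the frequency at which that feature was
sampled during the Monte Carlo trajectories; DRR > 1 means the design
process enriches the native beyond its sampling rate.  The antigen
risk ratio (ARR) compares native-feature recovery between simulations
run with and without the antigen; ARR > 1 means the antigen drives the
selection.  A per-residue sequence ARR aggregates the fraction of
decoys carrying the native residue type over CDR positions and
antibodies, computed separately for antigen-contacting and
non-contacting positions.

95% confidence intervals use the standard log-risk-ratio (Katz)
interval: CI = exp(ln RR +/- 1.96 * sqrt((1-p1)/(N1 p1) + (1-p2)/(N2 p2))).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import MetricsError

CONTACT_CUTOFF = 5.0     # heavy-atom contact definition for sequence ARR
Z_95 = 1.959963984540054

BENCHMARK_TABLE_SHA256 = (
    "090b94b753883244e9dadad9c89620627fd91d2c8208fdd75e8bd7ebd5c89d57")


@dataclass
class RecoveryCounts:
    """Raw recovery / sampling tallies for one CDR and feature."""

    feature: str          # length | cluster | residue
    cdr: str
    n_recovered: int
    n_total_decoys: int
    n_native_sampled: int = 0
    n_total_sampled: int = 0

    def __post_init__(self):
        if not (0 <= self.n_recovered <= self.n_total_decoys):
            raise MetricsError("recovered counts out of range")
        if not (0 <= self.n_native_sampled <= self.n_total_sampled):
            raise MetricsError("sampled counts out of range")

    @property
    def pct_recovered(self) -> float:
        return 100.0 * self.n_recovered / self.n_total_decoys

    @property
    def pct_sampled(self) -> float:
        if self.n_total_sampled == 0:
            raise MetricsError("no sampling attempts recorded")
        return 100.0 * self.n_native_sampled / self.n_total_sampled


@dataclass
class RiskRatio:
    """A ratio of two proportions with a 95% log-scale CI."""

    estimate: float
    ci_low: float
    ci_high: float
    p_num: float
    p_den: float
    n_num: int
    n_den: int

    def excludes_one(self) -> bool:
        return bool(np.isfinite(self.ci_low) and np.isfinite(self.ci_high)
                    and (self.ci_low > 1.0 or self.ci_high < 1.0))


def risk_ratio(p_num: float, n_num: int, p_den: float, n_den: int) -> RiskRatio:
    """Risk ratio of two proportions with the Katz log-scale 95% CI."""
    if p_den <= 0:
        raise MetricsError("risk ratio undefined: denominator proportion is 0")
    estimate = p_num / p_den
    if p_num <= 0 or n_num <= 0 or n_den <= 0 or p_num > 1 or p_den > 1:
        return RiskRatio(estimate, float("nan"), float("nan"),
                         p_num, p_den, n_num, n_den)
    se = np.sqrt((1.0 - p_num) / (n_num * p_num)
                 + (1.0 - p_den) / (n_den * p_den))
    return RiskRatio(
        estimate=float(estimate),
        ci_low=float(np.exp(np.log(estimate) - Z_95 * se)),
        ci_high=float(np.exp(np.log(estimate) + Z_95 * se)),
        p_num=float(p_num), p_den=float(p_den),
        n_num=int(n_num), n_den=int(n_den))


# ----------------------------------------------------------------------
# recovery bookkeeping


def recovery_rates(records_by_antibody: dict, native_by_antibody: dict,
                   cdrs=None) -> dict:
    """Tally recovery and sampling over a benchmark of design runs.

    ``records_by_antibody`` maps antibody id to its list of
    DesignRecords; ``native_by_antibody`` maps antibody id to
    ``{cdr: {"length": int, "cluster": str}}``.  Returns
    ``{(cdr, feature): RecoveryCounts}`` aggregated over all
    antibodies, for features ``length`` and ``cluster``.
    """
    all_cdrs = set()
    for records in records_by_antibody.values():
        for rec in records:
            all_cdrs.update(rec.sampled_counts)
    if cdrs is not None:
        all_cdrs = set(cdrs)
    out = {}
    for cdr in sorted(all_cdrs):
        for feature in ("length", "cluster"):
            n_rec = n_dec = n_nat = n_tot = 0
            for ab_id, records in records_by_antibody.items():
                native = native_by_antibody.get(ab_id, {}).get(cdr)
                if native is None:
                    raise MetricsError(
                        f"missing native {cdr} labels for {ab_id}")
                want = native[feature]
                for rec in records:
                    n_dec += 1
                    got = rec.final_labels.get(cdr, {}).get(
                        "cluster" if feature == "cluster" else "length")
                    if got == want:
                        n_rec += 1
                    tally = rec.sampled_counts.get(cdr)
                    if tally:
                        key = "clusters" if feature == "cluster" else "lengths"
                        n_tot += tally["attempts"]
                        n_nat += tally[key].get(want, 0)
            out[(cdr, feature)] = RecoveryCounts(
                feature=feature, cdr=cdr, n_recovered=n_rec,
                n_total_decoys=n_dec, n_native_sampled=n_nat,
                n_total_sampled=n_tot)
    return out


def design_risk_ratio(counts: RecoveryCounts) -> RiskRatio:
    """DRR = %Recovered / %Sampled with its 95% CI.

    The CI denominators are the total decoy count and the total
    graft-attempt count.
    """
    if counts.n_native_sampled == 0:
        raise MetricsError(
            f"DRR undefined for {counts.cdr}/{counts.feature}: native "
            "feature never sampled")
    return risk_ratio(counts.n_recovered / counts.n_total_decoys,
                      counts.n_total_decoys,
                      counts.n_native_sampled / counts.n_total_sampled,
                      counts.n_total_sampled)


def antigen_risk_ratio(with_ag: RecoveryCounts,
                       without_ag: RecoveryCounts) -> RiskRatio:
    """ARR = %Recovered(with antigen) / %Recovered(without antigen)."""
    if without_ag.n_recovered == 0:
        raise MetricsError("ARR undefined: zero recovery without antigen")
    return risk_ratio(with_ag.n_recovered / with_ag.n_total_decoys,
                      with_ag.n_total_decoys,
                      without_ag.n_recovered / without_ag.n_total_decoys,
                      without_ag.n_total_decoys)


def sequence_arr(fractions_with, fractions_without,
                 n_decoys: int = 100) -> RiskRatio:
    """Per-residue sequence ARR over a position table.

    Inputs are aligned mappings/Series ``(antibody, position) -> fraction
    of decoys with the native residue type`` from antigen-present and
    antigen-absent simulations.  The ARR is the ratio of the summed
    fractions.  The CI treats each table as a proportion over
    ``n_entries * n_decoys`` trials.
    """
    s_with = pd.Series(dict(fractions_with)).sort_index()
    s_without = pd.Series(dict(fractions_without)).sort_index()
    if len(s_with) == 0 or len(s_without) == 0:
        raise MetricsError("sequence ARR over an empty index set")
    if not s_with.index.equals(s_without.index):
        raise MetricsError("sequence ARR index sets differ")
    if ((s_with < 0) | (s_with > 1) | (s_without < 0) | (s_without > 1)).any():
        raise MetricsError("fractions must lie in [0, 1]")
    total_without = float(s_without.sum())
    if total_without <= 0:
        raise MetricsError("sequence ARR undefined: zero recovery without "
                           "antigen")
    n = len(s_with) * n_decoys
    return risk_ratio(float(s_with.mean()), n, float(s_without.mean()), n)


def contact_residues(native_complex, cutoff: float = CONTACT_CUTOFF) -> dict:
    """Per-CDR sets of positions contacting the antigen.

    A CDR position is contacting when any of its heavy atoms lies
    within ``cutoff`` of any antigen heavy atom.  Returns
    ``{cdr: {(chain, number_label), ...}}`` (empty sets when the
    antigen is absent).
    """
    from .model import CDR_REGIONS

    ag_atoms = [xyz for cid in native_complex.antigen_chain_ids
                for res in native_complex.chains[cid]
                for xyz in res.atoms.values()]
    out = {cdr: set() for cdr in CDR_REGIONS
           if native_complex.region_residues(cdr)}
    if not ag_atoms:
        return out
    tree = cKDTree(np.array(ag_atoms))
    for cdr in out:
        for res in native_complex.region_residues(cdr):
            dist, _ = tree.query(res.heavy_coords(), k=1)
            if np.min(dist) <= cutoff:
                out[cdr].add((res.chain_id, res.number_label))
    return out


# ----------------------------------------------------------------------
# benchmark-composition statistics


@dataclass
class BenchmarkRow:
    pdb_id: str
    vl: str
    h1: str
    h2: str
    h3: str       # length-only label like "H3-15"
    l1: str
    l2: str
    l3: str
    ag_length: int = 0
    antigen: str = ""

    def __post_init__(self):
        for attr in ("h1", "h2", "h3", "l1", "l2", "l3"):
            label = getattr(self, attr)
            parts = label.split("-")
            if len(parts) < 2 or not parts[1].isdigit():
                raise MetricsError(
                    f"malformed cluster label {label!r} in {self.pdb_id}")

    def cluster(self, cdr: str) -> str:
        return getattr(self, cdr.lower())

    def length(self, cdr: str) -> int:
        return int(self.cluster(cdr).split("-")[1])


NON_H3_CDRS = ("H1", "H2", "L1", "L2", "L3")


def load_benchmark_table() -> list:
    """The packaged 60-complex benchmark composition table.

    Guarded by a checksum so accidental edits of the fixture are
    caught.
    """
    ref = resources.files("cdrdesign.data") / "benchmark_complexes.tsv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != BENCHMARK_TABLE_SHA256:
        raise MetricsError(
            "benchmark composition table checksum mismatch: "
            f"{digest}")
    frame = pd.read_csv(ref.open("r"), sep="\t")
    return [BenchmarkRow(pdb_id=r["pdb"], vl=r["vl"], h1=r["h1"],
                         h2=r["h2"], h3=r["h3"], l1=r["l1"], l2=r["l2"],
                         l3=r["l3"], ag_length=int(r["ag_length"]),
                         antigen=str(r["antigen"]))
            for _, r in frame.iterrows()]


def benchmark_table_stats(rows) -> dict:
    """Composition summary of a benchmark table.

    Length classes are counted as distinct (CDR, length) pairs over the
    five non-H3 CDRs.
    """
    rows = list(rows)
    clusters = {(cdr, row.cluster(cdr)) for row in rows
                for cdr in NON_H3_CDRS}
    length_classes = {(cdr, row.length(cdr)) for row in rows
                      for cdr in NON_H3_CDRS}
    h3_lengths = [row.length("H3") for row in rows]
    return {
        "n_kappa": sum(1 for r in rows if r.vl == "kappa"),
        "n_lambda": sum(1 for r in rows if r.vl == "lambda"),
        "distinct_nonH3_clusters": len({c for _, c in clusters}),
        "distinct_nonH3_length_classes": len(length_classes),
        "h3_length_min": min(h3_lengths),
        "h3_length_max": max(h3_lengths),
    }
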