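"""Reproducible benchmark studies over the synthetic fixture suite.

These are the package's own desk-scale counterparts of full design
benchmarking: a graft-closure census, a Monte Carlo sampling
bookkeeping study, and the planted-native recovery study that
exercises the whole pipeline (graft sampling -> Metropolis acceptance
-> decoy selection -> risk-ratio statistics) under a controlled energy
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import grafting
from .database import CdrSet, CdrSetFilter, cull_all, query_cdrset
from .metrics import design_risk_ratio, recovery_rates
from .protocol import ProtocolConfig, run_design
from .scoring import ConstantEnergy
from .synthetic import (SyntheticSpec, default_composition,
                        make_synthetic_benchmark)


@dataclass
class ClosureCensus:
    n_grafts: int
    n_closed: int
    n_fallback: int
    max_internal_rmsd_ccd: float
    all_accepted_pass_criteria: bool

    @property
    def closure_rate(self) -> float:
        return self.n_closed / self.n_grafts


def graft_closure_census(n_grafts: int = 500, seed: int = 0,
                         benchmark=None) -> ClosureCensus:
    """Graft a random entry onto a random fixture antibody, n times.

    Every accepted (closed) graft is re-measured against the closure
    criteria; internal CDR RMSD is tracked for the CCD-closed subset.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
    bench = benchmark or make_synthetic_benchmark(
        SyntheticSpec(n_antibodies=4, entries_per_cdr=18, seed=seed))
    ab_ids = sorted(bench.antibodies)
    n_closed = n_fallback = 0
    max_rmsd = 0.0
    all_pass = True
    for _ in range(n_grafts):
        ab = bench.antibodies[ab_ids[int(rng.integers(len(ab_ids)))]]
        entry = bench.entries[int(rng.integers(len(bench.entries)))]
        result = grafting.graft_cdr(entry, ab, entry.cdr, rng=rng)
        if result.closed:
            n_closed += 1
            geom = grafting.measure_closure(result.complex, entry.cdr)
            if not grafting.check_closure(geom):
                all_pass = False
            if result.used_fallback:
                n_fallback += 1
            else:
                max_rmsd = max(max_rmsd, result.internal_rmsd)
    return ClosureCensus(n_grafts=n_grafts, n_closed=n_closed,
                         n_fallback=n_fallback,
                         max_internal_rmsd_ccd=max_rmsd,
                         all_accepted_pass_criteria=all_pass)


@dataclass
class BookkeepingStudy:
    per_cdr_attempts: dict
    n_antibodies: int
    n_runs: int
    n_outer: int

    @property
    def total_attempts(self) -> int:
        return sum(self.per_cdr_attempts.values())

    def expected_per_cdr(self) -> float:
        return (self.n_outer * self.n_runs * self.n_antibodies
                / len(self.per_cdr_attempts))

    def full_scale_expectation(self, n_runs_full: int = 100) -> float:
        """Expected attempts per CDR at the full benchmark scale."""
        return (self.n_outer * n_runs_full * self.n_antibodies
                / len(self.per_cdr_attempts))


def sampling_bookkeeping_study(n_antibodies: int = 60, n_runs: int = 10,
                               n_outer: int = 100, seed: int = 0
                               ) -> BookkeepingStudy:
    """Count graft attempts per CDR over a flat-energy benchmark run.

    All six CDRs are graft-designed with equal weights under a constant
    energy, so attempts split 1/6 per CDR in expectation.
    """
    bench = make_synthetic_benchmark(
        SyntheticSpec(n_antibodies=n_antibodies, entries_per_cdr=12,
                      seed=seed))
    entries = cull_all(bench.entries)
    cdrs = tuple(sorted(bench.spec.composition))
    cdrset = query_cdrset(entries, CdrSetFilter(min_cluster_members=1),
                          cdrs, "kappa")
    attempts = {cdr: 0 for cdr in cdrs}
    for index, ab_id in enumerate(sorted(bench.antibodies)):
        config = ProtocolConfig(
            n_outer=n_outer, n_struct=n_runs,
            seed=int(np.random.SeedSequence([seed, 41, index])
                     .generate_state(1)[0] % (2**31)),
            graft_design_cdrs=cdrs, seq_strategy="none")
        records = run_design(bench.antibodies[ab_id], cdrset,
                             ConstantEnergy(), config)
        for rec in records:
            for cdr, tally in rec.sampled_counts.items():
                attempts[cdr] += tally["attempts"]
    return BookkeepingStudy(per_cdr_attempts=attempts,
                            n_antibodies=n_antibodies, n_runs=n_runs,
                            n_outer=n_outer)


@dataclass
class PlantedRecoveryStudy:
    risk_ratio: object
    counts: object
    bonus: float
    n_decoys: int


def planted_recovery_study(bonus: float, seed: int = 0,
                           n_antibodies: int = 8, n_runs: int = 8,
                           n_outer: int = 25, cdr: str = "L1",
                           benchmark=None) -> PlantedRecoveryStudy:
    """End-to-end DRR for a planted-native synthetic benchmark.

    A single CDR is graft-designed under even-cluster sampling with a
    random-start graft (the native conformation is replaced by a random
    database entry before cycle 1, as in benchmark design runs --
    otherwise the native-started trajectory would trivially bias
    recovery).  The energy is a flat base plus the planted-native
    interface bonus (in kT units).  With a large bonus the native
    cluster should be enriched in the output decoys (DRR > 1); with
    bonus 0 the landscape is flat and the DRR must be statistically
    indistinguishable from 1.
    """
    spec = SyntheticSpec(
        n_antibodies=n_antibodies, entries_per_cdr=16, seed=seed,
        native_bonus=bonus,
        composition=default_composition(
            cdrs=(cdr,), lengths={cdr: (10, 11)}, clusters_per_length=2))
    bench = benchmark or make_synthetic_benchmark(spec)
    entries = cull_all(bench.entries)
    cdrset = query_cdrset(entries, CdrSetFilter(min_cluster_members=1),
                          (cdr,), "kappa")
    records_by_ab = {}
    for index, ab_id in enumerate(sorted(bench.antibodies)):
        hook = bench.energy_hook(ab_id)
        hook.bonus = float(bonus)
        config = ProtocolConfig(
            n_outer=n_outer, n_struct=n_runs,
            seed=int(np.random.SeedSequence([seed, 59, index])
                     .generate_state(1)[0] % (2**31)),
            graft_design_cdrs=(cdr,), seq_strategy="none",
            random_start=True)
        records_by_ab[ab_id] = run_design(bench.antibodies[ab_id], cdrset,
                                          hook, config)
    counts = recovery_rates(records_by_ab, bench.native_labels,
                            cdrs=(cdr,))[(cdr, "cluster")]
    rr = design_risk_ratio(counts)
    return PlantedRecoveryStudy(risk_ratio=rr, counts=counts, bonus=bonus,
                                n_decoys=counts.n_total_decoys)


def metropolis_frequency(delta_over_kt: float = 1.0, n_trials: int = 100_000,
                         seed: int = 0) -> float:
    """Observed Metropolis acceptance frequency at a fixed uphill step."""
    from .protocol import metropolis_accept

    rng = np.random.default_rng(np.random.SeedSequence([seed, 67]))
    hits = sum(metropolis_accept(0.0, delta_over_kt, 1.0, rng)
               for _ in range(n_trials))
    return hits / n_trials
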