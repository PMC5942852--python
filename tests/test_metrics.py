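"""Recovery statistics: DRR, ARR, CIs, contacts, benchmark composition."""

import numpy as np
import pytest

from cdrdesign.errors import MetricsError
from cdrdesign.metrics import (BenchmarkRow, RecoveryCounts,
                               antigen_risk_ratio, benchmark_table_stats,
                               contact_residues, design_risk_ratio,
                               load_benchmark_table, recovery_rates,
                               risk_ratio, sequence_arr)


def counts(feature="cluster", cdr="L1", rec=30, dec=100, nat=20, tot=100):
    return RecoveryCounts(feature=feature, cdr=cdr, n_recovered=rec,
                          n_total_decoys=dec, n_native_sampled=nat,
                          n_total_sampled=tot)


class TestRiskRatioArithmetic:
    def test_equal_proportions_give_one(self):
        rr = design_risk_ratio(counts(rec=20, dec=100, nat=20, tot=100))
        assert rr.estimate == pytest.approx(1.0)

    def test_thirty_over_twenty_gives_1p5(self):
        rr = design_risk_ratio(counts(rec=30, dec=100, nat=20, tot=100))
        assert rr.estimate == pytest.approx(1.5)

    def test_abstract_contact_recovery_arr_is_exactly_1p5(self):
        with_ag = RecoveryCounts("residue", "all", 72, 100)
        without = RecoveryCounts("residue", "all", 48, 100)
        arr = antigen_risk_ratio(with_ag, without)
        assert arr.estimate == 72 / 48 == 1.5

    def test_zero_native_sampled_is_flagged(self):
        with pytest.raises(MetricsError):
            design_risk_ratio(counts(nat=0))

    def test_zero_recovery_without_antigen_is_flagged(self):
        with pytest.raises(MetricsError):
            antigen_risk_ratio(RecoveryCounts("cluster", "L1", 10, 100),
                               RecoveryCounts("cluster", "L1", 0, 100))

    def test_ci_brackets_estimate(self):
        rr = design_risk_ratio(counts())
        assert rr.ci_low <= rr.estimate <= rr.ci_high


def bootstrap_ci(p1, n1, p2, n2, n_rep=100_000, seed=0):
    """Parametric bootstrap of a ratio of two binomial proportions."""
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(n1, p1, size=n_rep) / n1
    x2 = rng.binomial(n2, p2, size=n_rep) / n2
    ok = (x1 > 0) & (x2 > 0)
    ratios = x1[ok] / x2[ok]
    return np.quantile(ratios, [0.025, 0.975])


class TestConfidenceIntervals:
    def test_drr_ci_matches_parametric_bootstrap(self):
        c = counts(rec=300, dec=1000, nat=200, tot=1000)
        rr = design_risk_ratio(c)
        lo, hi = bootstrap_ci(0.3, 1000, 0.2, 1000)
        assert rr.ci_low == pytest.approx(lo, abs=0.01)
        assert rr.ci_high == pytest.approx(hi, abs=0.01)

    def test_arr_ci_matches_parametric_bootstrap(self):
        with_ag = RecoveryCounts("cluster", "L1", 720, 1000)
        without = RecoveryCounts("cluster", "L1", 480, 1000)
        arr = antigen_risk_ratio(with_ag, without)
        lo, hi = bootstrap_ci(0.72, 1000, 0.48, 1000, seed=1)
        assert arr.ci_low == pytest.approx(lo, abs=0.01)
        assert arr.ci_high == pytest.approx(hi, abs=0.01)

    def test_abstract_scale_arr_ci(self):
        # at the benchmark scale (6000 decoys) the 1.5 ratio is tightly
        # bounded away from 1
        with_ag = RecoveryCounts("residue", "all", 4320, 6000)
        without = RecoveryCounts("residue", "all", 2880, 6000)
        arr = antigen_risk_ratio(with_ag, without)
        assert arr.estimate == pytest.approx(1.5)
        assert arr.excludes_one()
        lo, hi = bootstrap_ci(0.72, 6000, 0.48, 6000, seed=2)
        assert arr.ci_low == pytest.approx(lo, abs=0.01)
        assert arr.ci_high == pytest.approx(hi, abs=0.01)


class FakeRecord:
    def __init__(self, final, sampled):
        self.final_labels = final
        self.sampled_counts = sampled


def fake_record(cluster, length, attempts):
    sampled = {"L1": {"attempts": sum(attempts.values()),
                      "lengths": {}, "clusters": dict(attempts)}}
    for cid, n in attempts.items():
        ln = int(cid.split("-")[1])
        sampled["L1"]["lengths"][ln] = sampled["L1"]["lengths"].get(ln, 0) + n
    return FakeRecord({"L1": {"cluster": cluster, "length": length}},
                      sampled)


class TestRecoveryRates:
    NATIVE = {"ab": {"L1": {"cluster": "L1-11-1", "length": 11}}}

    def test_all_native_decoys_give_full_recovery(self):
        records = [fake_record("L1-11-1", 11, {"L1-11-1": 2, "L1-10-1": 3})
                   for _ in range(10)]
        out = recovery_rates({"ab": records}, self.NATIVE)
        assert out[("L1", "cluster")].pct_recovered == 100.0

    def test_hand_built_counts(self):
        records = ([fake_record("L1-11-1", 11, {"L1-11-1": 2, "L1-10-1": 8})]
                   * 3 + [fake_record("L1-10-1", 10,
                                      {"L1-11-1": 2, "L1-10-1": 8})] * 7)
        out = recovery_rates({"ab": records}, self.NATIVE)
        c = out[("L1", "cluster")]
        assert c.n_recovered == 3 and c.n_total_decoys == 10
        assert c.n_native_sampled == 20 and c.n_total_sampled == 100
        assert design_risk_ratio(c).estimate == pytest.approx(1.5)

    def test_matches_independent_tally_on_synthetic_records(self, rng):
        clusters = ["L1-11-1", "L1-10-1", "L1-10-2"]
        records = []
        for _ in range(500):
            final = clusters[int(rng.integers(3))]
            attempts = {c: int(rng.integers(1, 10)) for c in clusters}
            records.append(fake_record(final, int(final.split("-")[1]),
                                       attempts))
        out = recovery_rates({"ab": records}, self.NATIVE)
        want_rec = sum(1 for r in records
                       if r.final_labels["L1"]["cluster"] == "L1-11-1")
        want_nat = sum(r.sampled_counts["L1"]["clusters"]["L1-11-1"]
                       for r in records)
        want_tot = sum(r.sampled_counts["L1"]["attempts"] for r in records)
        c = out[("L1", "cluster")]
        assert (c.n_recovered, c.n_native_sampled, c.n_total_sampled) == (
            want_rec, want_nat, want_tot)

    def test_missing_native_labels_raise(self):
        records = [fake_record("L1-11-1", 11, {"L1-11-1": 1})]
        with pytest.raises(MetricsError):
            recovery_rates({"ab": records}, {"ab": {}})


class TestSequenceArr:
    def test_identical_tables_give_one(self):
        table = {("a", 1): 0.5, ("a", 2): 0.25}
        assert sequence_arr(table, table).estimate == pytest.approx(1.0)

    def test_2x2_table_sums(self):
        with_ag = {("a", 1): 0.9, ("a", 2): 0.9}
        without = {("a", 1): 0.6, ("a", 2): 0.6}
        assert sequence_arr(with_ag, without).estimate == pytest.approx(1.5)

    def test_matches_brute_force_double_sum(self, rng):
        keys = [(f"ab{i}", pos) for i in range(5) for pos in range(8)]
        w = {k: float(rng.uniform(0.1, 1.0)) for k in keys}
        wo = {k: float(rng.uniform(0.1, 1.0)) for k in keys}
        want = sum(w.values()) / sum(wo.values())
        assert sequence_arr(w, wo).estimate == pytest.approx(want, abs=1e-12)

    def test_empty_index_raises(self):
        with pytest.raises(MetricsError):
            sequence_arr({}, {})


class TestContactResidues:
    def test_no_antigen_gives_empty_sets(self, scaffold_no_antigen):
        out = contact_residues(scaffold_no_antigen)
        assert all(not positions for positions in out.values())

    def test_boundary_distance(self):
        from cdrdesign.model import AntibodyComplex, Residue

        def res(chain, label, xyz, region="framework"):
            return Residue(chain_id=chain, seq_position=1, number=label,
                           aa="G", region=region,
                           atoms={"CA": np.asarray(xyz, float)})

        cx = AntibodyComplex(
            {"H": [res("H", 27, [0, 0, 0], "H1"),
                   res("H", 28, [5.1, 0, 0], "H1")],
             "G": [res("G", 1, [0.0, 4.9, 0.0], "antigen")]},
            {"H": "heavy", "G": "antigen"})
        out = contact_residues(cx, cutoff=5.0)
        assert ("H", "27") in out["H1"]
        assert ("H", "28") not in out["H1"]

    def test_equals_brute_force_scan(self, scaffold):
        got = contact_residues(scaffold, cutoff=5.0)
        ag = [xyz for cid in scaffold.antigen_chain_ids
              for r in scaffold.chains[cid] for xyz in r.atoms.values()]
        ag = np.array(ag)
        for cdr, positions in got.items():
            want = set()
            for r in scaffold.region_residues(cdr):
                d = np.linalg.norm(r.heavy_coords()[:, None] - ag[None],
                                   axis=2)
                if d.min() <= 5.0:
                    want.add((r.chain_id, r.number_label))
            assert positions == want


class TestBenchmarkTable:
    def test_packaged_composition_statistics(self):
        stats = benchmark_table_stats(load_benchmark_table())
        assert stats["n_kappa"] == 46
        assert stats["n_lambda"] == 14
        assert stats["distinct_nonH3_clusters"] == 35
        assert stats["h3_length_min"] == 6
        assert stats["h3_length_max"] == 24

    def test_single_row_table(self):
        row = BenchmarkRow(pdb_id="1abc", vl="kappa", h1="H1-13-1",
                           h2="H2-10-1", h3="H3-12", l1="L1-11-1",
                           l2="L2-8-1", l3="L3-9-cis7-1")
        stats = benchmark_table_stats([row])
        assert stats["distinct_nonH3_clusters"] == 5
        assert stats["h3_length_min"] == stats["h3_length_max"] == 12

    def test_cis_labels_encode_length_correctly(self):
        row = BenchmarkRow(pdb_id="1abc", vl="kappa", h1="H1-13-1",
                           h2="H2-10-1", h3="H3-12", l1="L1-11-1",
                           l2="L2-8-1", l3="L3-9-cis7-1")
        assert row.length("L3") == 9

    def test_malformed_label_rejected(self):
        with pytest.raises(MetricsError):
            BenchmarkRow(pdb_id="1abc", vl="kappa", h1="bad", h2="H2-10-1",
                         h3="H3-12", l1="L1-11-1", l2="L2-8-1",
                         l3="L3-9-1")

    def test_risk_ratio_guard_against_bad_proportions(self):
        with pytest.raises(MetricsError):
            risk_ratio(0.5, 100, 0.0, 100)
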