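"""Monte Carlo design engine: acceptance, sampling, trajectories."""

import numpy as np
import pytest
from scipy.stats import chisquare

from cdrdesign.database import CdrSetFilter, build_profiles, cull_all, query_cdrset
from cdrdesign.errors import ConfigError
from cdrdesign.protocol import (ProtocolConfig, acceptance_energy,
                                choose_cdr, choose_graft_source,
                                metropolis_accept, prepare_complex,
                                run_design, score_table)
from cdrdesign.scoring import ConstantEnergy, ReferenceEnergy


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert metropolis_accept(10.0, 5.0, 1.0, rng)

    def test_infinite_uphill_never_accepted(self, rng):
        assert not metropolis_accept(0.0, np.inf, 1.0, rng)

    def test_acceptance_frequency_at_delta_equals_kT(self):
        rng = np.random.default_rng(2024)
        n = 100_000
        accepted = sum(metropolis_accept(0.0, 1.0, 1.0, rng)
                       for _ in range(n))
        assert accepted / n == pytest.approx(np.exp(-1.0), abs=0.005)

    def test_zero_kT_is_greedy(self, rng):
        assert not metropolis_accept(0.0, 1e-9, 0.0, rng)
        assert metropolis_accept(0.0, -1e-9, 0.0, rng)


class TestChooseCdr:
    def test_single_cdr_always_chosen(self, rng):
        assert choose_cdr({"L1": 1.0}, rng) == "L1"

    def test_equal_weights_are_uniform(self):
        rng = np.random.default_rng(77)
        weights = {c: 1.0 for c in ("L1", "L2", "L3", "H1", "H2", "H3")}
        n = 60_000
        counts = {c: 0 for c in weights}
        for _ in range(n):
            counts[choose_cdr(weights, rng)] += 1
        assert chisquare(list(counts.values())).pvalue > 0.01

    def test_two_to_one_weighting(self):
        rng = np.random.default_rng(78)
        n = 30_000
        hits = sum(choose_cdr({"L1": 2.0, "H2": 1.0}, rng) == "L1"
                   for _ in range(n))
        assert hits / n == pytest.approx(2.0 / 3.0, abs=0.01)

    def test_all_zero_weights_rejected(self, rng):
        with pytest.raises(ConfigError):
            choose_cdr({"L1": 0.0, "L2": 0.0}, rng)


class TestChooseGraftSource:
    @staticmethod
    def skewed_cdrset(small_benchmark):
        """A two-cluster L1 set with a 10%/90% entry split."""
        from cdrdesign.database import CdrSet

        by_cluster = {}
        for e in small_benchmark.entries:
            if e.cdr == "L1":
                by_cluster.setdefault(e.cluster_id, []).append(e)
        ids = sorted(by_cluster)[:2]
        small = by_cluster[ids[0]][:2]
        big = (by_cluster[ids[1]] * 7)[:18]
        assert len(small) == 2 and len(big) == 18
        return CdrSet(entries={"L1": small + big}), ids

    def test_even_cluster_mc_draws_clusters_uniformly(self,
                                                      small_benchmark):
        cdrset, ids = self.skewed_cdrset(small_benchmark)
        rng = np.random.default_rng(5)
        n = 10_000
        hits = sum(choose_graft_source(cdrset, "L1", "even_cluster_mc",
                                       rng).cluster_id == ids[0]
                   for _ in range(n))
        assert chisquare([hits, n - hits]).pvalue > 0.01  # ~50/50

    def test_gen_mc_draws_by_database_frequency(self, small_benchmark):
        cdrset, ids = self.skewed_cdrset(small_benchmark)
        rng = np.random.default_rng(6)
        n = 10_000
        hits = sum(choose_graft_source(cdrset, "L1", "gen_mc",
                                       rng).cluster_id == ids[0]
                   for _ in range(n))
        assert chisquare([hits, n - hits],
                         [0.1 * n, 0.9 * n]).pvalue > 0.01

    def test_single_entry_always_returned(self, small_benchmark, rng):
        from cdrdesign.database import CdrSet

        entry = small_benchmark.entries[0]
        cdrset = CdrSet(entries={entry.cdr: [entry]})
        for algo in ("even_cluster_mc", "gen_mc",
                     "even_length_cluster_mc"):
            assert choose_graft_source(cdrset, entry.cdr, algo, rng) is entry

    def test_deterministic_graft_enumerates_sequentially(self,
                                                         small_benchmark):
        from cdrdesign.database import CdrSet

        entries = [e for e in small_benchmark.entries if e.cdr == "L2"][:5]
        cdrset = CdrSet(entries={"L2": entries})
        rng = np.random.default_rng(0)
        got = [choose_graft_source(cdrset, "L2", "deterministic_graft",
                                   rng, counter=i) for i in range(5)]
        assert got == entries

    def test_deterministic_graft_multi_cdr_config_rejected(self):
        with pytest.raises(ConfigError):
            ProtocolConfig(graft_algorithm="deterministic_graft",
                           graft_design_cdrs=("L1", "H2"))


class TestPrepareComplex:
    def test_energy_non_increasing_and_rmsd_small(self, scaffold):
        model = ReferenceEnergy()
        before = model.score(scaffold)
        prepared, rmsd = prepare_complex(scaffold, model)
        after = model.score(prepared)
        assert after <= before + 1e-9
        assert rmsd <= 0.3

    def test_already_minimal_system_unchanged(self):
        # two far-apart single-residue chains sit at a flat optimum
        from cdrdesign.model import AntibodyComplex, Residue

        a = Residue(chain_id="A", seq_position=1, number=1, aa="G",
                    atoms={"CA": np.array([0.0, 0.0, 0.0])})
        b = Residue(chain_id="B", seq_position=1, number=1, aa="G",
                    atoms={"CA": np.array([50.0, 0.0, 0.0])})
        cx = AntibodyComplex({"A": [a], "B": [b]},
                             {"A": "heavy", "B": "antigen"})
        prepared, rmsd = prepare_complex(cx, ReferenceEnergy())
        assert rmsd == pytest.approx(0.0, abs=1e-9)


def quick_config(**kw):
    base = dict(n_outer=5, n_struct=2, seed=42, graft_design_cdrs=("L1",),
                seq_design_cdrs=(), seq_strategy="none")
    base.update(kw)
    return ProtocolConfig(**base)


@pytest.fixture(scope="module")
def l1_setup(l1_benchmark):
    entries = cull_all(l1_benchmark.entries)
    cdrset = query_cdrset(entries, CdrSetFilter(min_cluster_members=1),
                          ["L1"], "kappa")
    profiles = build_profiles(entries)
    return l1_benchmark, cdrset, profiles


class TestRunDesign:
    def test_zero_outer_cycles_returns_input_state(self, l1_setup):
        bench, cdrset, _ = l1_setup
        ab = bench.antibodies["ab000"]
        records = run_design(ab, cdrset, ConstantEnergy(),
                             quick_config(n_outer=0, n_struct=1))
        assert len(records) == 1
        assert records[0].graft_history == []

    def test_run_produces_requested_decoys_with_history(self, l1_setup):
        bench, cdrset, _ = l1_setup
        ab = bench.antibodies["ab000"]
        records = run_design(ab, cdrset, ConstantEnergy(), quick_config())
        assert len(records) == 2
        for rec in records:
            assert rec.sampled_counts["L1"]["attempts"] == 5
            closed = [ev for ev in rec.graft_history if ev["closed"]]
            assert closed  # at least some grafts must close

    def test_identical_seed_gives_byte_identical_score_files(self,
                                                             l1_setup):
        bench, cdrset, _ = l1_setup
        ab = bench.antibodies["ab001"]
        tables = []
        for _ in range(2):
            records = run_design(ab, cdrset, ConstantEnergy(),
                                 quick_config())
            tables.append(score_table(records).to_csv(sep="\t", index=False))
        assert tables[0] == tables[1]

    def test_best_record_energy_bounds_accepted_states(self, l1_setup):
        bench, cdrset, _ = l1_setup
        ab = bench.antibodies["ab000"]
        energy = bench.energy_hook("ab000")
        records = run_design(ab, cdrset, energy,
                             quick_config(n_outer=10, n_struct=2))
        for rec in records:
            # the output is the minimum-acceptance-energy state visited
            assert rec.acceptance_energy <= 0.0  # start state energy

    def test_zero_temperature_trajectory_is_monotone(self, l1_setup):
        bench, cdrset, _ = l1_setup
        ab = bench.antibodies["ab000"]
        energy = bench.energy_hook("ab000")
        config = quick_config(n_outer=12, n_struct=1, kT=0.0)
        records = run_design(ab, cdrset, energy, config)
        # with kT -> 0 every accepted move is downhill, so the best
        # energy equals the final accepted energy
        rec = records[0]
        assert rec.acceptance_energy <= 0.0

    def test_antigen_absent_mode_strips_antigen(self, l1_setup):
        bench, cdrset, _ = l1_setup
        ab = bench.antibodies["ab000"]
        config = quick_config(antigen_present=False, n_struct=1)
        records = run_design(ab, cdrset, ConstantEnergy(), config)
        assert not records[0].complex.antigen_chain_ids
        assert records[0].dG_interface is None

    def test_graft_attempt_counts_follow_weights(self, small_benchmark):
        entries = cull_all(small_benchmark.entries)
        cdrset = query_cdrset(entries, CdrSetFilter(min_cluster_members=1),
                              ["L1", "H2"], "kappa")
        ab = small_benchmark.antibodies["ab000"]
        config = ProtocolConfig(n_outer=60, n_struct=4, seed=3,
                                graft_design_cdrs=("L1", "H2"),
                                cdr_weights={"L1": 2.0, "H2": 1.0},
                                seq_strategy="none")
        records = run_design(ab, cdrset, ConstantEnergy(), config)
        l1 = sum(r.sampled_counts["L1"]["attempts"] for r in records)
        h2 = sum(r.sampled_counts["H2"]["attempts"] for r in records)
        assert chisquare([l1, h2], [160, 80]).pvalue > 0.01


class TestAcceptanceEnergy:
    def test_opt_dg_differs_from_opt_e(self, scaffold):
        model = ReferenceEnergy()
        total = acceptance_energy(scaffold, model,
                                  quick_config(acceptance_mode="opt_E"))
        dg = acceptance_energy(scaffold, model,
                               quick_config(acceptance_mode="opt_dG"))
        assert total == pytest.approx(model.score(scaffold))
        assert dg != pytest.approx(total)

    def test_weighted_combination(self, scaffold):
        model = ReferenceEnergy()
        e = acceptance_energy(scaffold, model,
                              quick_config(acceptance_mode="opt_E"))
        dg = acceptance_energy(scaffold, model,
                               quick_config(acceptance_mode="opt_dG"))
        mixed = acceptance_energy(
            scaffold, model, quick_config(acceptance_mode="weighted",
                                          acceptance_weight=0.25))
        assert mixed == pytest.approx(0.75 * e + 0.25 * dg, abs=1e-9)

    def test_without_antigen_falls_back_to_total(self, scaffold_no_antigen):
        model = ReferenceEnergy()
        got = acceptance_energy(scaffold_no_antigen, model,
                                quick_config(acceptance_mode="opt_dG"))
        assert got == pytest.approx(model.score(scaffold_no_antigen))
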