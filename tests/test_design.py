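"""Design operations: palettes, masks, packing shells, the packer."""

import numpy as np
import pytest

from cdrdesign.database import ClusterProfile
from cdrdesign.design import (build_design_mask, conservative_palette,
                              conservative_set, native_palette,
                              pack_and_design, packing_shell,
                              profile_palette)
from cdrdesign.errors import DirectiveError, PaletteError
from cdrdesign.model import AMINO_ACIDS
from cdrdesign.scoring import ConstantEnergy, EnergyModel
from cdrdesign.sidechain import set_residue_type


class TestConservativeSets:
    def test_isoleucine_row(self):
        assert conservative_set("I") == set("ILMVF")

    def test_tryptophan_row(self):
        assert conservative_set("W") == set("WYF")

    @pytest.mark.parametrize("aa", list(AMINO_ACIDS))
    def test_always_contains_self(self, aa):
        assert aa in conservative_set(aa)

    def test_unknown_code_rejected(self):
        with pytest.raises(PaletteError):
            conservative_set("X")


def uniform_profile(cluster_id, length, types):
    counts = np.zeros((length, 20))
    for aa in types:
        counts[:, AMINO_ACIDS.index(aa)] = 1
    return ClusterProfile(cluster_id=cluster_id, n_sequences=50,
                          counts=counts, pseudocount=0.0)


class TestProfilePalette:
    def test_delta_profile_gives_native_only(self, rng):
        counts = np.zeros((3, 20))
        for pos, aa in enumerate("ADE"):
            counts[pos, AMINO_ACIDS.index(aa)] = 10
        profile = ClusterProfile("L1-3-1", n_sequences=10, counts=counts,
                                 pseudocount=0.0)
        pal = profile_palette(profile, "ADE", rounds=50, rng=rng)
        assert pal.allowed == [{"A"}, {"D"}, {"E"}]

    def test_uniform_two_type_profile_allows_both(self, rng):
        profile = uniform_profile("L1-4-1", 4, "AG")
        pal = profile_palette(profile, "AAAA", rounds=50, rng=rng)
        for allowed in pal.allowed:
            assert allowed == {"A", "G"}

    def test_native_always_included(self, rng):
        profile = uniform_profile("L1-4-1", 4, "DE")
        pal = profile_palette(profile, "WWWW", rounds=5, rng=rng)
        for allowed in pal.allowed:
            assert "W" in allowed

    def test_same_seed_reproduces_palette(self):
        profile = uniform_profile("L1-6-1", 6, "ADEF")
        a = profile_palette(profile, "AAAAAA", 3,
                            np.random.default_rng(9))
        b = profile_palette(profile, "AAAAAA", 3,
                            np.random.default_rng(9))
        assert a.allowed == b.allowed

    def test_sampling_frequencies_match_profile(self):
        # chi-square on 1e5 draws from one position of a skewed profile
        from scipy.stats import chisquare

        counts = np.zeros((1, 20))
        counts[0, AMINO_ACIDS.index("A")] = 60
        counts[0, AMINO_ACIDS.index("D")] = 30
        counts[0, AMINO_ACIDS.index("E")] = 10
        profile = ClusterProfile("L2-1-1", n_sequences=100, counts=counts,
                                 pseudocount=0.0)
        rng = np.random.default_rng(17)
        draws = [profile.sample_position(0, rng) for _ in range(100_000)]
        observed = [draws.count(aa) for aa in "ADE"]
        expected = [60_000, 30_000, 10_000]
        assert chisquare(observed, expected).pvalue > 0.01

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(PaletteError):
            profile_palette(uniform_profile("L1-4-1", 4, "A"), "ADE", 5, rng)


class TestDesignMask:
    def test_h3_stem_never_designable(self, scaffold):
        mask = build_design_mask(scaffold, ["H3"])
        h3 = scaffold.region_residues("H3")
        keys = [(r.chain_id, r.number_label) for r in h3]
        for k in (keys[0], keys[1], keys[-3], keys[-2], keys[-1]):
            assert mask.of(k) == "repack_only"
        for k in keys[2:-3]:
            assert mask.of(k) == "design"

    def test_proline_disabled(self, small_benchmark):
        from cdrdesign.synthetic import (SyntheticSpec,
                                         make_synthetic_benchmark)

        spec = SyntheticSpec(n_antibodies=1, entries_per_cdr=6, seed=3,
                             plant_proline=True)
        bench = make_synthetic_benchmark(spec)
        cx = bench.antibodies["ab000"]
        mask = build_design_mask(cx, ["L1"])
        pro = [r for r in cx.region_residues("L1") if r.aa == "P"]
        assert pro
        for r in pro:
            assert mask.of((r.chain_id, r.number_label)) == "repack_only"

    def test_disulfide_cysteines_disabled(self):
        from cdrdesign.synthetic import (SyntheticSpec,
                                         make_synthetic_benchmark)

        spec = SyntheticSpec(n_antibodies=1, entries_per_cdr=6, seed=3,
                             plant_disulfide=True)
        bench = make_synthetic_benchmark(spec)
        cx = bench.antibodies["ab000"]
        mask = build_design_mask(cx, ["L1"])
        cys = [r for r in cx.region_residues("L1") if r.aa == "C"]
        assert len(cys) == 2
        for r in cys:
            key = (r.chain_id, r.number_label)
            assert mask.of(key) == "repack_only"
            assert mask.auto_disabled[key] == "disulfide"

    def test_override_fixes_position(self, scaffold):
        l1 = scaffold.region_residues("L1")
        key = (l1[4].chain_id, l1[4].number_label)
        mask = build_design_mask(scaffold, ["L1"],
                                 overrides=f"{key[0]} {key[1]} FIX")
        assert mask.of(key) == "fixed"
        others = [(r.chain_id, r.number_label) for r in l1
                  if (r.chain_id, r.number_label) != key]
        assert all(mask.of(k) in ("design", "repack_only") for k in others)

    def test_unknown_residue_in_override_raises(self, scaffold):
        with pytest.raises(DirectiveError):
            build_design_mask(scaffold, ["L1"], overrides="Z 999 FIX")


class TestPackingShell:
    def test_shell_equals_brute_force_scan(self, scaffold):
        shell = packing_shell(scaffold, "L1", neighbor_cdrs=("L3",))
        core = (scaffold.region_residues("L1")
                + scaffold.region_residues("L3"))
        core_xyz = np.vstack([r.heavy_coords() for r in core])
        want = {(r.chain_id, r.number_label) for r in core}
        for res in scaffold.residues():
            d = np.linalg.norm(res.heavy_coords()[:, None, :]
                               - core_xyz[None, :, :], axis=2)
            if d.min() <= 6.0:
                want.add((res.chain_id, res.number_label))
        assert shell == want

    def test_boundary_distance_is_inclusive_six(self):
        from cdrdesign.model import AntibodyComplex, Residue

        def lone(chain_id, label, x, region="framework"):
            return Residue(chain_id=chain_id, seq_position=1, number=label,
                           aa="G", region=region,
                           atoms={"CA": np.array([x, 0.0, 0.0])})

        focus = lone("A", 27, 0.0, region="L1")
        near = lone("A", 90, -6.0)     # exactly at the cutoff: included
        far = lone("A", 91, 6.05)      # just outside: excluded
        cx = AntibodyComplex({"A": [focus, near, far]}, {"A": "light"})
        shell = packing_shell(cx, "L1")
        assert ("A", "90") in shell
        assert ("A", "91") not in shell


class PairTableEnergy(EnergyModel):
    """Toy energy defined purely by the residue types at two positions."""

    def __init__(self, keys, table):
        self.keys = keys
        self.table = table

    def score(self, complex_, chain_ids=None):
        aa = {}
        for res in complex_.residues():
            if (res.chain_id, res.number_label) in self.keys:
                aa[(res.chain_id, res.number_label)] = res.aa
        pair = tuple(aa[k] for k in self.keys)
        return self.table.get(pair, 5.0)


class TestPackAndDesign:
    def test_singleton_palette_changes_nothing(self, scaffold, rng):
        mask = build_design_mask(scaffold, ["L1"])
        shell = packing_shell(scaffold, "L1")
        l1 = scaffold.region_residues("L1")
        palette = {(r.chain_id, r.number_label): {r.aa} for r in l1}
        before = {(r.chain_id, r.number_label): r.aa
                  for r in scaffold.residues()}
        out = pack_and_design(scaffold, palette, mask, shell,
                              ConstantEnergy(), rng)
        after = {(r.chain_id, r.number_label): r.aa
                 for r in out.residues()}
        assert before == after

    def test_separable_toy_matches_exhaustive_enumeration(self, scaffold,
                                                           rng):
        # an additive (separable) pair table: greedy sweeps provably
        # reach the global optimum, which the oracle enumerates
        l1 = scaffold.region_residues("L1")
        keys = [(l1[3].chain_id, l1[3].number_label),
                (l1[4].chain_id, l1[4].number_label)]
        types = ["A", "D", "E", "F"]
        trng = np.random.default_rng(5)
        f = {a: float(trng.uniform(-3, 3)) for a in types + [l1[3].aa]}
        g = {b: float(trng.uniform(-3, 3)) for b in types + [l1[4].aa]}
        table = {(a, b): f.get(a, 5.0) + g.get(b, 5.0)
                 for a in f for b in g}
        energy = PairTableEnergy(keys, table)
        mask = build_design_mask(scaffold, ["L1"])
        palette = {k: set(types) for k in keys}
        out = pack_and_design(scaffold, palette, mask, set(keys), energy,
                              rng, sweeps=2)
        got = tuple(res.aa for res in out.residues()
                    if (res.chain_id, res.number_label) in keys)
        want = min(table, key=table.get)
        assert table[got] == pytest.approx(table[want])

    def test_random_pair_tables_match_exhaustive_enumeration(self,
                                                              scaffold):
        # coupled two-residue tables are inside the exact-search bound,
        # so the packer must return the enumeration optimum every time
        l1 = scaffold.region_residues("L1")
        keys = [(l1[3].chain_id, l1[3].number_label),
                (l1[4].chain_id, l1[4].number_label)]
        types = ["A", "D", "E", "F"]
        mask = build_design_mask(scaffold, ["L1"])
        palette = {k: set(types) for k in keys}
        for trial in range(20):
            trng = np.random.default_rng(100 + trial)
            table = {(a, b): float(trng.uniform(-3, 3))
                     for a in types + [l1[3].aa] for b in types + [l1[4].aa]}
            energy = PairTableEnergy(keys, table)
            out = pack_and_design(scaffold, palette, mask, set(keys),
                                  energy, np.random.default_rng(trial),
                                  sweeps=3)
            got = tuple(res.aa for res in out.residues()
                        if (res.chain_id, res.number_label) in keys)
            assert table.get(got, 5.0) == pytest.approx(min(table.values()))

    def test_energy_non_increasing_across_commits(self, scaffold, rng):
        energies = []

        class Recorder(EnergyModel):
            def __init__(self, keys, table):
                self.inner = PairTableEnergy(keys, table)

            def score(self, complex_, chain_ids=None):
                return self.inner.score(complex_, chain_ids)

        l1 = scaffold.region_residues("L1")
        keys = [(l1[3].chain_id, l1[3].number_label),
                (l1[4].chain_id, l1[4].number_label)]
        table = {(a, b): float(np.random.default_rng(8).uniform(-2, 2))
                 for a in "ADE" for b in "ADE"}
        energy = Recorder(keys, table)
        mask = build_design_mask(scaffold, ["L1"])
        palette = {k: set("ADE") for k in keys}
        state = scaffold
        prev = energy.score(state)
        for _ in range(3):
            state = pack_and_design(state, palette, mask, set(keys),
                                    energy, rng, sweeps=1)
            now = energy.score(state)
            assert now <= prev + 1e-12
            prev = now

    def test_native_fallback_palettes(self):
        pal = conservative_palette("IW")
        assert pal.allowed == [set("ILMVF"), set("WYF")]
        pal = native_palette("IW")
        assert pal.allowed == [{"I"}, {"W"}]
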