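"""Reference energy, interface energy, buried surface, interface residues."""

import numpy as np
import pytest

from cdrdesign.model import AntibodyComplex, Residue
from cdrdesign.errors import InterfaceError
from cdrdesign.scoring import (CLASH_SCALE, AtomTable, ReferenceEnergy,
                               buried_surface_area, interface_energy,
                               interface_residues, reference_score,
                               atom_radius)


def rigid_residue(chain_id, label, offset, region="framework", aa="G"):
    base = np.asarray(offset, float)
    return Residue(chain_id=chain_id, seq_position=label, number=label,
                   aa=aa, region=region,
                   atoms={"N": base + [0.0, 0, 0],
                          "CA": base + [1.46, 0, 0],
                          "C": base + [2.0, 1.4, 0],
                          "O": base + [1.5, 2.4, 0.4]})


def point_residue(chain_id, label, xyz, aa="G", atom="CA"):
    res = Residue(chain_id=chain_id, seq_position=label, number=label,
                  aa=aa, atoms={atom: np.asarray(xyz, float)})
    return res


def two_chain_system(separation):
    a = [rigid_residue("A", i + 1, [4.0 * i, 0, 0]) for i in range(3)]
    b = [rigid_residue("B", i + 1, [4.0 * i, separation, 0])
         for i in range(3)]
    return AntibodyComplex({"A": a, "B": b},
                           {"A": "heavy", "B": "antigen"})


def two_point_system(separation):
    a = [point_residue("A", 1, [0.0, 0.0, 0.0])]
    b = [point_residue("B", 1, [0.0, separation, 0.0])]
    return AntibodyComplex({"A": a, "B": b},
                           {"A": "heavy", "B": "antigen"})


class TestReferenceEnergy:
    def test_distant_atoms_contribute_nothing(self):
        cx = two_chain_system(50.0)
        bd = reference_score(cx)
        # intra-chain terms exist; inter-chain must add nothing:
        bd_a = reference_score(cx, chain_ids=["A"])
        bd_b = reference_score(cx, chain_ids=["B"])
        assert bd.total == pytest.approx(bd_a.total + bd_b.total, abs=1e-9)

    def test_clash_formula_at_sixty_percent_overlap(self):
        # two isolated single-atom residues at 60% of the radius sum:
        # penalty = k * ((R - d) / R)^2 with R the scaled radius sum
        radius_sum = atom_radius("N", "G") + atom_radius("N", "G")
        R = CLASH_SCALE * radius_sum
        d = 0.6 * radius_sum
        r1 = point_residue("A", 1, [0.0, 0.0, 0.0], atom="N")
        r2 = point_residue("B", 1, [d, 0.0, 0.0], atom="N")
        cx = AntibodyComplex({"A": [r1], "B": [r2]},
                             {"A": "heavy", "B": "antigen"})
        model = ReferenceEnergy(contact_weight=0.0, hbond_weight=0.0)
        bd = model.breakdown(cx)
        want = model.clash_weight * ((R - d) / R) ** 2
        assert bd.clash == pytest.approx(want, abs=1e-9)
        assert bd.clash > 0

    def test_rigid_motion_invariance(self, scaffold):
        from scipy.spatial.transform import Rotation

        model = ReferenceEnergy()
        before = model.score(scaffold)
        rot = Rotation.from_euler("xyz", [11, 23, -37],
                                  degrees=True).as_matrix()
        moved = scaffold.copy()
        for res in moved.residues():
            for name, xyz in res.atoms.items():
                res.atoms[name] = rot @ xyz + np.array([5.0, -3.0, 8.0])
        after = model.score(moved)
        assert after == pytest.approx(before, abs=1e-6)

    def test_breakdown_total_is_sum_of_terms(self, scaffold):
        bd = reference_score(scaffold)
        assert bd.total == pytest.approx(
            bd.clash + bd.contact + bd.hbond_proxy + bd.reference, abs=1e-9)

    def test_additivity_at_500A_separation(self, scaffold):
        model = ReferenceEnergy()
        moved = scaffold.copy()
        for cid in moved.antigen_chain_ids:
            for res in moved.chains[cid]:
                for name, xyz in res.atoms.items():
                    res.atoms[name] = xyz + np.array([500.0, 0.0, 0.0])
        total = model.score(moved)
        parts = (model.score(moved, moved.antibody_chain_ids)
                 + model.score(moved, moved.antigen_chain_ids))
        assert total == pytest.approx(parts, abs=1e-9)

    def test_gradient_matches_finite_differences(self, scaffold):
        model = ReferenceEnergy()
        table = AtomTable.from_complex(scaffold)
        e0, grad = model.energy_and_grad(table)
        rng = np.random.default_rng(3)
        for _ in range(5):
            i = int(rng.integers(len(table.positions)))
            axis = int(rng.integers(3))
            h = 1e-6
            table.positions[i, axis] += h
            e1, _ = model.energy_and_grad(table)
            table.positions[i, axis] -= h
            fd = (e1 - e0) / h
            assert fd == pytest.approx(grad[i, axis], abs=1e-3)


class TestInterfaceEnergy:
    def test_separated_chains_have_zero_dG(self):
        cx = two_chain_system(50.0)
        assert interface_energy(cx, ReferenceEnergy()) == pytest.approx(
            0.0, abs=1e-9)

    def test_interchain_clash_increases_dG(self):
        near = two_chain_system(1.0)   # overlapping backbones
        apart = two_chain_system(7.0)
        model = ReferenceEnergy(contact_weight=0.0, hbond_weight=0.0)
        assert interface_energy(near, model) > interface_energy(apart, model)

    def test_contact_well_depth_closed_form(self):
        # one interaction-center pair inside the saturated contact well
        r1 = rigid_residue("A", 1, [0, 0, 0], aa="A")
        r2 = rigid_residue("B", 1, [0, 0, 0], aa="A")
        for res, shift in ((r1, 0.0), (r2, 5.0)):
            res.atoms.clear()
            res.atoms["CA"] = np.array([shift, 0.0, 0.0])
        cx = AntibodyComplex({"A": [r1], "B": [r2]},
                             {"A": "heavy", "B": "antigen"})
        model = ReferenceEnergy(clash_weight=0.0, hbond_weight=0.0,
                                contact_weight=0.7)
        # d = 5.0 < 5.5: full well depth = -0.7
        assert interface_energy(cx, model) == pytest.approx(-0.7, abs=1e-9)

    def test_single_chain_complex_rejected(self):
        a = [rigid_residue("A", 1, [0, 0, 0])]
        cx = AntibodyComplex({"A": a}, {"A": "heavy"})
        with pytest.raises(InterfaceError):
            interface_energy(cx, ReferenceEnergy())


class TestBuriedSurface:
    def test_isolated_atom_area_is_analytic_sphere(self):
        r = rigid_residue("A", 1, [0, 0, 0])
        r.atoms = {"N": np.array([0.0, 0.0, 0.0])}
        b = rigid_residue("B", 1, [200.0, 0, 0])
        b.atoms = {"N": np.array([200.0, 0.0, 0.0])}
        cx = AntibodyComplex({"A": [r], "B": [b]},
                             {"A": "heavy", "B": "antigen"})
        from cdrdesign.scoring import _sasa

        radius = atom_radius("N", "G") + 1.4
        want = 4.0 * np.pi * radius ** 2
        got = _sasa(cx, ["A"], probe_radius=1.4, point_number=960)
        assert got == pytest.approx(want, rel=0.01)

    def test_far_chains_bury_nothing(self):
        cx = two_chain_system(80.0)
        assert buried_surface_area(cx) == pytest.approx(0.0, abs=1e-6)

    def test_two_overlapping_spheres_match_fine_grid_oracle(self):
        r1 = rigid_residue("A", 1, [0, 0, 0])
        r1.atoms = {"C": np.array([0.0, 0.0, 0.0])}
        r2 = rigid_residue("B", 1, [0, 0, 0])
        r2.atoms = {"C": np.array([2.5, 0.0, 0.0])}
        cx = AntibodyComplex({"A": [r1], "B": [r2]},
                             {"A": "heavy", "B": "antigen"})
        got = buried_surface_area(cx, point_number=960)
        # analytic buried cap area for two equal spheres of radius R
        # centered d apart: each sphere loses a cap of height h =
        # R - d/2; buried = 2 * 2*pi*R*h
        R = atom_radius("C", "G") + 1.4
        h = R - 2.5 / 2.0
        want = 2.0 * 2.0 * np.pi * R * h
        assert got == pytest.approx(want, rel=0.02)

    def test_burial_grows_monotonically_on_approach(self, scaffold):
        areas = []
        for shift in (50.0, 20.0, 5.0, 0.0):
            moved = scaffold.copy()
            for cid in moved.antigen_chain_ids:
                for res in moved.chains[cid]:
                    for name, xyz in res.atoms.items():
                        res.atoms[name] = xyz + np.array([shift, 0, 0])
            areas.append(buried_surface_area(moved, point_number=240))
        assert areas[0] == pytest.approx(0.0, abs=0.05)
        assert areas[1] <= areas[2] + 0.05
        assert areas[2] <= areas[3] + 0.05
        assert areas[3] > 10.0


class TestInterfaceResidues:
    def test_far_chains_give_empty_set(self):
        assert interface_residues(two_chain_system(60.0)) == set()

    def test_boundary_at_eight_angstroms(self):
        # single-atom chains so the pair distance is exactly the shift
        assert interface_residues(two_point_system(7.9), distance=8.0) == {
            (("A", "1"), ("B", "1"))}
        assert not interface_residues(two_point_system(8.1), distance=8.0)

    def test_equals_brute_force_scan(self, scaffold):
        got = interface_residues(scaffold, distance=8.0)
        want = set()
        ab = [r for cid in scaffold.antibody_chain_ids
              for r in scaffold.chains[cid]]
        ag = [r for cid in scaffold.antigen_chain_ids
              for r in scaffold.chains[cid]]
        for ra in ab:
            xa = ra.heavy_coords()
            for rg in ag:
                xg = rg.heavy_coords()
                d = np.linalg.norm(xa[:, None] - xg[None, :], axis=2)
                if d.min() <= 8.0:
                    want.add(((ra.chain_id, ra.number_label),
                              (rg.chain_id, rg.number_label)))
        assert got == want
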