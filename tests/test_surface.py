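import math

import numpy as np
import pytest

from hotsite.fixtures import FixtureSpec, build_helix, make_dimer
from hotsite.structure import Atom, Partition, Residue, Structure
from hotsite.surface import (contacts, half_sphere_exposure, hydrogen_bonds,
                             pseudo_cbeta, residue_depth, shrake_rupley_sasa,
                             surface_profile)


def _single_atom_structure(element="C", radius=1.7):
    atom = Atom("CA", element, np.zeros(3), radius)
    res = Residue("A", 1, " ", "A", "ALA", [atom])
    return Structure([res])


def _atoms_structure(coords, radius=1.7):
    residues = []
    for i, c in enumerate(coords):
        atom = Atom("CA", "C", np.asarray(c, dtype=float), radius)
        residues.append(Residue("A", i + 1, " ", "A", "ALA", [atom]))
    return Structure(residues)


class TestShrakeRupley:
    def test_isolated_sphere_closed_form(self):
        st = _single_atom_structure()
        sasa = shrake_rupley_sasa(st, probe_radius=1.4, n_sphere_points=960)
        expected = 4 * math.pi * 3.1 ** 2  # ~120.76
        assert sasa.residue_area(("A", 1, " ")) == pytest.approx(expected,
                                                                 rel=1e-9)

    def test_distant_atoms_unperturbed(self):
        st = _atoms_structure([[0, 0, 0], [10, 0, 0]])  # > 2*(1.7+1.4)
        sasa = shrake_rupley_sasa(st)
        expected = 4 * math.pi * 3.1 ** 2
        for rid in (("A", 1, " "), ("A", 2, " ")):
            assert sasa.residue_area(rid) == pytest.approx(expected, rel=1e-9)

    def test_resolution_convergence(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(scale=1.5, size=(5, 3))
        st = _atoms_structure(coords)
        lo = shrake_rupley_sasa(st, n_sphere_points=960)
        hi = shrake_rupley_sasa(st, n_sphere_points=10_000)
        for rid in lo.residue_totals():
            assert lo.residue_area(rid) == pytest.approx(
                hi.residue_area(rid), rel=0.02)

    def test_validation(self):
        st = _single_atom_structure()
        with pytest.raises(ValueError):
            shrake_rupley_sasa(st, probe_radius=0)
        with pytest.raises(ValueError):
            shrake_rupley_sasa(st, n_sphere_points=10)
        with pytest.raises(ValueError):
            shrake_rupley_sasa(Structure([]))


class TestSurfaceProfile:
    def test_weights_normalize(self, dimer):
        prof = surface_profile(dimer)
        assert sum(prof.W[r] for r in prof.interface) == pytest.approx(
            1.0, abs=1e-9)
        assert all(prof.W[r] == 0 for r in prof.W
                   if r not in prof.interface)

    def test_delta_asa_nonnegative(self, dimer):
        prof = surface_profile(dimer)
        assert min(prof.delta_asa.values()) >= -1e-9

    def test_wfb_formula(self, dimer):
        # independent recomputation of Eq-style arithmetic
        prof = surface_profile(dimer)
        for rid in prof.interface:
            expected = (prof.W[rid] * prof.delta_asa[rid]
                        / prof.asa_monomer[rid])
            assert prof.W_FB[rid] == pytest.approx(expected, rel=1e-12)
        # direct arithmetic example: W=0.5, dASA=50, ASA_m=100 -> 0.25
        assert 0.5 * 50 / 100 == pytest.approx(0.25)

    def test_no_interface_errors(self):
        st = make_dimer(FixtureSpec(seed=0, gap=30.0))
        with pytest.raises(ValueError, match="no interface"):
            surface_profile(st)


class TestHalfSphereExposure:
    def test_isolated_residue_zero(self):
        res = build_helix(1)[0]
        st = Structure([res])
        hse = half_sphere_exposure(st)
        rid = res.rid
        assert hse.CN[rid] == 0
        assert hse.HSEAU[rid] == 0 and hse.HSEAD[rid] == 0
        assert hse.HSEBU[rid] == 0 and hse.HSEBD[rid] == 0

    def test_constructed_upper_neighbor(self):
        # neighbor CA placed along the central residue's CA->CB direction
        center = build_helix(1)[0]
        ca = center.atom("CA").coord
        cb = center.atom("CB").coord
        direction = (cb - ca) / np.linalg.norm(cb - ca)
        nb_ca = ca + 5.0 * direction
        nb = Residue("B", 1, " ", "A", "ALA",
                     [Atom("CA", "C", nb_ca, 1.7)])
        st = Structure([center, nb])
        hse = half_sphere_exposure(st, radius=13.0)
        assert hse.HSEAU[center.rid] == 1 and hse.HSEAD[center.rid] == 0
        assert hse.HSEBU[center.rid] == 1 and hse.HSEBD[center.rid] == 0
        assert hse.CN[center.rid] == 1

    def test_brute_force_oracle(self):
        helix = build_helix(20)
        st = Structure(helix)
        radius = 13.0
        hse = half_sphere_exposure(st, radius=radius)
        # exhaustive pairwise enumeration oracle for CN and HSEB
        for res in helix:
            ca = res.atom("CA").coord
            u = pseudo_cbeta(res) - ca
            cn = bu = 0
            for other in helix:
                if other.rid == res.rid:
                    continue
                rel = other.atom("CA").coord - ca
                if np.linalg.norm(rel) <= radius:
                    cn += 1
                    if np.dot(u, rel) > 0:
                        bu += 1
            assert hse.CN[res.rid] == cn
            assert hse.HSEBU[res.rid] == bu
            assert hse.HSEBD[res.rid] == cn - bu

    def test_updown_sums_to_cn(self, dimer):
        hse = half_sphere_exposure(dimer)
        for rid, cn in hse.CN.items():
            assert hse.HSEBU[rid] + hse.HSEBD[rid] == cn
            assert hse.HSEAU[rid] + hse.HSEAD[rid] == cn


class TestResidueDepth:
    def test_single_residue_minimal(self):
        st = _single_atom_structure()
        rd, rda = residue_depth(st)
        assert rd[("A", 1, " ")] == pytest.approx(1.4)  # probe offset only
        assert rda[("A", 1, " ")] == pytest.approx(1.4)

    def test_buried_deeper_than_exposed(self):
        # inner atom surrounded by a shell of outer atoms
        from hotsite.surface import sphere_points
        shell = 4.0 * sphere_points(40)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        st = _atoms_structure(coords)
        rd, _ = residue_depth(st)
        inner = rd[("A", 1, " ")]
        outer = [rd[("A", i, " ")] for i in range(2, 42)]
        assert inner > max(outer)

    def test_surface_residue_probe_offset(self, dimer):
        prof_rd, _ = residue_depth(dimer)
        assert min(prof_rd.values()) >= 1.4 - 1e-9


class TestContacts:
    def test_isolated_residue_zero(self):
        st = _single_atom_structure()
        prof = contacts(st)
        rid = ("A", 1, " ")
        assert prof.atom_complex[rid] == 0
        assert prof.Ncrc[rid] == 0 and prof.Delncr[rid] == 0

    def test_identical_environment_delta_zero(self):
        # far-apart dimer: no cross-side contacts -> monomer == complex
        st = make_dimer(FixtureSpec(seed=0, gap=30.0))
        prof = contacts(st)
        for rid in prof.Delncr:
            assert prof.Delncr[rid] == pytest.approx(0.0)
            assert prof.Delnac[rid] == pytest.approx(0.0)

    def test_brute_force_oracle(self, dimer):
        atom_cutoff, residue_cutoff = 4.5, 6.5
        prof = contacts(dimer, atom_cutoff, residue_cutoff)
        residues = dimer.residues[:8]
        for res in residues:
            n_atom = 0
            for other in dimer.residues:
                if other.rid == res.rid:
                    continue
                for a in res.heavy_atoms:
                    for b in other.heavy_atoms:
                        if np.linalg.norm(a.coord - b.coord) <= atom_cutoff:
                            n_atom += 1
            assert prof.atom_complex[res.rid] == n_atom
            cb = pseudo_cbeta(res)
            n_res = sum(
                1 for other in dimer.residues
                if other.rid != res.rid
                and np.linalg.norm(pseudo_cbeta(other) - cb) <= residue_cutoff)
            assert prof.residue_complex[res.rid] == n_res

    def test_symmetric_at_pair_level(self, dimer):
        prof = contacts(dimer)
        total_pairs = sum(prof.atom_complex.values())
        assert total_pairs % 2 == 0  # every pair counted on both residues


class TestHydrogenBonds:
    def test_distant_residues_none(self):
        a = build_helix(1, "A")[0]
        b_res = build_helix(1, "B")[0]
        for atom in b_res.atoms:
            atom.coord[0] += 20.0
        st = Structure([a, b_res])
        counts = hydrogen_bonds(st)
        assert counts[a.rid] == 0 and counts[b_res.rid] == 0

    def test_constructed_backbone_bond(self):
        # donor backbone N 2.9 A from acceptor O, antecedent behind donor
        donor = Residue("A", 1, " ", "A", "ALA", [
            Atom("N", "N", np.array([0.0, 0.0, 0.0]), 1.55),
            Atom("CA", "C", np.array([-1.45, 0.0, 0.0]), 1.7),
        ])
        acceptor = Residue("B", 5, " ", "A", "ALA", [
            Atom("O", "O", np.array([2.9, 0.0, 0.0]), 1.52),
            Atom("C", "C", np.array([3.9, 0.9, 0.0]), 1.7),
        ])
        st = Structure([donor, acceptor])
        counts = hydrogen_bonds(st)
        assert counts[donor.rid] == 1
        assert counts[acceptor.rid] == 1

    def test_angle_rule_rejects(self):
        # antecedent between donor and acceptor -> angle < 90 deg
        donor = Residue("A", 1, " ", "A", "ALA", [
            Atom("N", "N", np.array([0.0, 0.0, 0.0]), 1.55),
            Atom("CA", "C", np.array([1.45, 0.0, 0.0]), 1.7),
        ])
        acceptor = Residue("B", 5, " ", "A", "ALA", [
            Atom("O", "O", np.array([2.9, 0.0, 0.0]), 1.52),
        ])
        st = Structure([donor, acceptor])
        counts = hydrogen_bonds(st)
        assert counts[donor.rid] == 0

    def test_brute_force_oracle_helix(self, dimer):
        # helix backbone i,i+4 N-H...O=C ladder: every bond symmetric
        counts = hydrogen_bonds(dimer)
        assert sum(counts.values()) % 2 == 0
        assert sum(counts.values()) > 0  # ideal helix has backbone bonds
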