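import math

import numpy as np
import pytest

from hotsite import descriptors as D
from hotsite.fixtures import (build_helix, write_disembl, write_disopred,
                              write_dssp, write_hb2, write_pssm)
from hotsite.neighbors import euclidean_neighbors
from hotsite.structure import Structure


class TestPhysicochemical:
    def test_deterministic_lookup(self):
        np.testing.assert_array_equal(D.physicochemical("W"),
                                      D.physicochemical("W"))

    def test_polarity_from_shipped_table(self):
        # spot values of the Grantham polarity column
        idx = D.PHYSCHEM_NAMES.index("Polarity")
        assert D.physicochemical("D")[idx] == 13.0
        assert D.physicochemical("L")[idx] == 4.9
        polarities = [D.physicochemical(a)[idx] for a in D.AA_ORDER]
        assert len(set(polarities)) >= 18  # near-unique across the 20 types

    def test_atom_count_ordering(self):
        idx = D.PHYSCHEM_NAMES.index("NumAtoms")
        assert D.physicochemical("G")[idx] < D.physicochemical("W")[idx]

    def test_nonstandard_sentinel(self):
        assert np.isnan(D.physicochemical("X")).all()
        assert np.isnan(D.pka_values("X")).all()

    def test_pka_lookup(self):
        pka = D.pka_values("G")
        assert pka[0] == pytest.approx(2.34)
        assert pka[1] == pytest.approx(9.60)


class TestConservation:
    def _profile(self, row):
        freqs = np.array([row], dtype=float)
        return D.PSSMProfile(sequence="A", scores=np.zeros((1, 20)),
                             freqs=freqs)

    def test_fully_conserved_zero(self):
        row = [0.0] * 20
        row[0] = 1.0
        assert D.conservation_score(self._profile(row), 1) == 0.0

    def test_uniform_maximum_entropy(self):
        row = [1 / 20] * 20
        assert D.conservation_score(self._profile(row), 1) == pytest.approx(
            math.log2(20), rel=1e-12)

    def test_binary_entropy(self):
        row = [0.0] * 20
        row[0] = row[1] = 0.5
        assert D.conservation_score(self._profile(row), 1) == pytest.approx(1.0)

    def test_all_zero_row_errors(self):
        with pytest.raises(ValueError):
            D.conservation_score(self._profile([0.0] * 20), 1)

    def test_position_out_of_range(self):
        with pytest.raises(IndexError):
            D.conservation_score(self._profile([1 / 20] * 20), 2)

    def test_bounds_random(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(20))
            score = D.conservation_score(self._profile(p), 1)
            assert 0 <= score <= math.log2(20) + 1e-12


class TestBlosum:
    def test_tryptophan_diagonal(self):
        row = D.blosum_row("W")
        assert row[D.AA_ORDER.index("W")] == 11

    def test_symmetry(self):
        for a, b in [("A", "T"), ("W", "C"), ("K", "R")]:
            assert (D.blosum_row(a)[D.AA_ORDER.index(b)]
                    == D.blosum_row(b)[D.AA_ORDER.index(a)])


class TestPssmReader:
    def test_round_trip(self, tmp_path):
        seq = "ACDEFGHIKL"
        path = tmp_path / "toy.pssm"
        written = write_pssm(path, seq, seed=5)
        pssm = D.read_pssm(path)
        assert pssm.sequence == seq
        np.testing.assert_allclose(pssm.freqs, written, atol=1e-9)

    def test_uniform_gives_max_entropy(self, tmp_path):
        path = tmp_path / "uni.pssm"
        write_pssm(path, "ACDE", uniform=True)
        pssm = D.read_pssm(path)
        for pos in range(1, 5):
            assert D.conservation_score(pssm, pos) == pytest.approx(
                math.log2(20), rel=1e-12)

    def test_pssm_row_bounds(self, tmp_path):
        path = tmp_path / "toy.pssm"
        write_pssm(path, "ACD", seed=1)
        pssm = D.read_pssm(path)
        assert D.pssm_row(pssm, 1).shape == (20,)
        with pytest.raises(IndexError):
            D.pssm_row(pssm, 4)

    def test_frequency_validation(self):
        with pytest.raises(ValueError):
            D.PSSMProfile("A", np.zeros((1, 20)),
                          np.full((1, 20), 0.5))  # sums to 10


class TestSecondaryStructure:
    @pytest.mark.parametrize("letter,expected", [
        ("H", (1, 0, 0)), ("G", (1, 0, 0)), ("I", (1, 0, 0)),
        ("E", (0, 1, 0)), ("B", (0, 1, 0)),
        ("T", (0, 0, 1)), ("S", (0, 0, 1)), (" ", (0, 0, 1)),
    ])
    def test_dssp_letter_mapping(self, letter, expected):
        onehot = D.secondary_structure(D._ss_class(letter))
        np.testing.assert_array_equal(onehot, expected)
        assert onehot.sum() == 1

    def test_helix_fallback(self):
        st = Structure(build_helix(10))
        ss = D.assign_secondary_structure(st)
        assert set(ss.values()) == {"H"}

    def test_sheet_fallback(self):
        st = Structure(build_helix(10, phi=-120.0, psi=130.0))
        ss = D.assign_secondary_structure(st)
        assert set(ss.values()) == {"E"}

    def test_dssp_track_wins(self, dimer, tracks_dir):
        dssp = D.read_dssp(tracks_dir / "structure.dssp")
        ss = D.assign_secondary_structure(dimer, dssp)
        assert set(ss.values()) == {"H"}  # fixture writes all-helix


class TestDsspReader:
    def test_round_trip(self, tmp_path, dimer):
        path = tmp_path / "toy.dssp"
        ss = {r.rid: ("E" if r.seq_number % 2 else "H")
              for r in dimer.residues}
        acc = {r.rid: float(r.seq_number) for r in dimer.residues}
        write_dssp(path, dimer, ss=ss, acc=acc)
        parsed = D.read_dssp(path)
        for r in dimer.residues:
            assert parsed[r.rid][0] == ss[r.rid]
            assert parsed[r.rid][1] == acc[r.rid]


class TestDisorder:
    def test_constant_track(self, tmp_path):
        seq = "ACDEF"
        p1, p2 = tmp_path / "x.diso", tmp_path / "x.disembl"
        write_disopred(p1, seq, scores=np.full(5, 0.5))
        write_disembl(p2, seq, tracks=np.full((5, 3), 0.5))
        rows_o = D.read_disopred(p1)
        rows_e = D.read_disembl(p2)
        for pos in range(1, 6):
            vec = D.disorder_scores(rows_o, rows_e, pos)
            np.testing.assert_allclose(vec[[0, 2, 3, 4, 5]], 0.5)

    def test_short_track_warns_and_sentinels(self, tmp_path):
        p1, p2 = tmp_path / "s.diso", tmp_path / "s.disembl"
        write_disopred(p1, "AC", seed=0)
        write_disembl(p2, "AC", seed=0)
        rows_o, rows_e = D.read_disopred(p1), D.read_disembl(p2)
        with pytest.warns(UserWarning, match="beyond disorder track"):
            vec = D.disorder_scores(rows_o, rows_e, 3)
        assert np.isnan(vec).all()


class TestResidueTsv:
    def test_order_invariance(self, tmp_path):
        ordered = tmp_path / "a.tsv"
        shuffled = tmp_path / "b.tsv"
        header = "chain resnum icode SCE1 SCE2\n"
        rows = ["A 1 - 0.1 0.2\n", "A 2 - 0.3 0.4\n", "B 1 - 0.5 0.6\n"]
        ordered.write_text(header + "".join(rows))
        shuffled.write_text(header + "".join(reversed(rows)))
        assert D.read_residue_tsv(ordered) == D.read_residue_tsv(shuffled)

    def test_bad_header(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("foo bar\n")
        with pytest.raises(ValueError):
            D.read_residue_tsv(p)


class TestHb2Reader:
    def test_round_trip_counts(self, tmp_path, dimer):
        path = tmp_path / "toy.hb2"
        bonds = [
            (("A", 2, " "), "N", ("B", 3, " "), "O"),
            (("A", 2, " "), "N", ("B", 5, " "), "O"),
            (("B", 3, " "), "N", ("A", 7, " "), "O"),
        ]
        write_hb2(path, bonds, structure=dimer)
        counts = D.read_hb2(path)
        assert counts[("A", 2, " ")] == 2
        assert counts[("B", 3, " ")] == 2
        assert counts[("A", 7, " ")] == 1
        assert counts[("B", 5, " ")] == 1


class TestPairPotential:
    def test_isolated_residue_zero(self):
        helix = build_helix(1)
        st = Structure(helix)
        g = euclidean_neighbors(st)
        np.testing.assert_array_equal(
            D.pair_potential(st, g, helix[0]), [0.0, 0.0, 0.0])

    def test_same_environment_difference_zero(self, dimer):
        # residues with no cross-side neighbors: Ppc == Ppm
        g = euclidean_neighbors(dimer)
        for res in dimer.residues:
            sides = {dimer.side_of(dimer.by_rid()[nb])
                     for nb in g.neighbors(res.rid)}
            if sides <= {dimer.side_of(res)}:
                vec = D.pair_potential(dimer, g, res)
                assert vec[2] == pytest.approx(0.0)

    def test_hand_summed_oracle(self, dimer):
        mat = D.default_pair_potential_matrix()
        g = euclidean_neighbors(dimer)
        res = dimer.residues[0]
        neighbors = g.neighbors(res.rid)
        by_rid = dimer.by_rid()
        expected_ppc = sum(mat[(res.aa_type, by_rid[nb].aa_type)]
                           for nb in neighbors)
        vec = D.pair_potential(dimer, g, res)
        assert vec[1] == pytest.approx(expected_ppc)

    def test_matrix_is_configurable(self, dimer):
        g = euclidean_neighbors(dimer)
        flat = {(a, b): 1.0 for a in D.AA_ORDER for b in D.AA_ORDER}
        res = dimer.residues[0]
        vec = D.pair_potential(dimer, g, res, matrix=flat)
        assert vec[1] == len(g.neighbors(res.rid))


def test_site_feature_list_fixed():
    assert len(D.SITE_FEATURES) == 102
    assert len(set(D.SITE_FEATURES)) == 102
    # representative members from each block
    for name in ("Hydrophobicity", "Pka1", "PssmQ", "Cscore", "Wfb",
                 "Delncr", "Ppm", "SCE5", "LSE3", "VorCross", "SS3",
                 "Disorder6", "BlosumW", "HSEBU", "Conservation", "Hb"):
        assert name in D.SITE_FEATURES
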