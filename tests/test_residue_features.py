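"""Geometric/physico-chemical features: contacts, coordination numbers,
pair potentials, accessibility, and the redundancy filter."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hotregions import (
    ComplexStructure,
    PairPotentialMatrix,
    ResidueId,
    ResidueRecord,
    ca_distance,
    compute_asa,
    contact_indicator,
    contact_map,
    coordination_numbers,
    load_max_asa,
    pair_potentials,
    pearson_redundancy_filter,
    relative_complex_asa,
)
from hotregions.residue_features import CaOnlyStructureError, MatrixCoverageError


def _structure(positions, chains=None, seq_nums=None, types=None, name="toy"):
    n = len(positions)
    chains = chains or ["A"] * n
    seq_nums = seq_nums or list(range(1, n + 1))
    types = types or ["GLY"] * n
    recs = [
        ResidueRecord(ResidueId(c, s, res_type=t), np.asarray(p, dtype=float))
        for c, s, t, p in zip(chains, seq_nums, types, positions)
    ]
    return ComplexStructure(name, recs)


class TestCaDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 0, 0), (3, 4, 0), 5.0),
            ((1, 2, 2), (0, 0, 0), 3.0),
            ((1.5, -2.5, 7.0), (1.5, -2.5, 7.0), 0.0),
        ],
    )
    def test_euclidean(self, a, b, expected):
        s = _structure([a, b])
        assert ca_distance(s.residues[0], s.residues[1]) == pytest.approx(expected)


class TestContacts:
    def test_sequence_neighbours_never_contact(self):
        s = _structure([(0, 0, 0), (1, 0, 0)], seq_nums=[5, 6])
        i, j = s.ids()
        assert contact_indicator(i, j, s) == 0

    def test_cutoff_boundary_inclusive(self):
        s = _structure([(0, 0, 0), (6.5, 0, 0)], seq_nums=[3, 10])
        i, j = s.ids()
        assert contact_indicator(i, j, s) == 1

    def test_above_cutoff(self):
        s = _structure([(0, 0, 0), (6.6, 0, 0)], seq_nums=[3, 10])
        i, j = s.ids()
        assert contact_indicator(i, j, s) == 0

    def test_strict_boundary_flag(self):
        s = _structure([(0, 0, 0), (6.5, 0, 0)], seq_nums=[3, 10])
        i, j = s.ids()
        assert contact_indicator(i, j, s, inclusive=False) == 0

    def test_cross_chain_always_sequence_eligible(self):
        s = _structure([(0, 0, 0), (3, 0, 0)], chains=["A", "B"], seq_nums=[1, 1])
        i, j = s.ids()
        assert contact_indicator(i, j, s) == 1

    def test_contact_map_matches_bruteforce_on_random_structure(self):
        rng = np.random.default_rng(42)
        n = 50
        pos = rng.uniform(0, 25, size=(n, 3))
        chains = ["A" if i < 25 else "B" for i in range(n)]
        seq = [i % 25 + 1 for i in range(n)]
        s = _structure(pos, chains=chains, seq_nums=seq)
        cm = contact_map(s)
        ids = cm.ids
        for a, b in itertools.combinations(range(n), 2):
            expected = contact_indicator(ids[a], ids[b], s)
            assert cm.matrix[a, b] == cm.matrix[b, a] == bool(expected)
        assert not cm.matrix.diagonal().any()


class TestCoordinationNumbers:
    def test_single_residue(self):
        cn = coordination_numbers(_structure([(0, 0, 0)]))
        assert list(cn.cn.values()) == [0]

    def test_straight_chain_all_zero(self):
        # consecutive Calpha 3.8 apart: every |i-j| >= 2 pair is >= 7.6 away
        s = _structure([(3.8 * i, 0, 0) for i in range(10)])
        cn = coordination_numbers(s)
        assert all(v == 0 for v in cn.cn.values())

    def test_clique_with_nonadjacent_numbering(self):
        pos = [(0, 0, 0), (3, 0, 0), (0, 3, 0), (3, 3, 0)]
        s = _structure(pos, seq_nums=[1, 5, 9, 13])
        cn = coordination_numbers(s)
        assert all(v == 3 for v in cn.cn.values())

    def test_equals_contact_map_row_sums(self, synthetic_complex):
        s = synthetic_complex.structure
        cm = contact_map(s)
        cn = coordination_numbers(s)
        for rid, total in zip(cm.ids, cm.row_sums()):
            assert cn[rid] == total


class TestPairPotentials:
    def _matrix(self, value=-3.0):
        types = ("ALA", "GLY")
        vals = {(a, b): value for a in types for b in types}
        return PairPotentialMatrix(values=vals, residue_types=types)

    def test_no_partner_within_cutoff_gives_zero(self):
        s = _structure([(0, 0, 0), (100, 0, 0)], seq_nums=[1, 10])
        pp = pair_potentials(s, self._matrix())
        assert pp[s.ids()[0]] == 0.0

    def test_close_pair_below_min_separation_excluded(self):
        s = _structure([(0, 0, 0), (3, 0, 0)], seq_nums=[1, 3])  # separation 2
        pp = pair_potentials(s, self._matrix())
        assert pp[s.ids()[0]] == 0.0

    def test_absolute_sum_of_matrix_entries(self):
        types = ["ALA", "GLY", "ALA"]
        vals = {
            ("ALA", "ALA"): -3.0,
            ("ALA", "GLY"): 1.0,
            ("GLY", "ALA"): 1.0,
            ("GLY", "GLY"): 0.5,
        }
        matrix = PairPotentialMatrix(values=vals, residue_types=("ALA", "GLY"))
        s = _structure(
            [(0, 0, 0), (3, 0, 0), (0, 3, 0)], seq_nums=[1, 10, 20], types=types
        )
        pp = pair_potentials(s, matrix)
        # residue 1 (ALA): partners GLY (+1.0) and ALA (-3.0) -> |sum| = 2.0
        assert pp[s.ids()[0]] == pytest.approx(2.0)

    def test_uncovered_type_raises(self):
        s = _structure([(0, 0, 0), (3, 0, 0)], seq_nums=[1, 10], types=["TRP", "TRP"])
        with pytest.raises(MatrixCoverageError):
            pair_potentials(s, self._matrix())

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 15, size=(8, 3))
        s1 = _structure(pos, seq_nums=[1, 6, 11, 16, 21, 26, 31, 36])
        # random rotation + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pos @ q.T + np.array([5.0, -3.0, 12.0])
        s2 = _structure(moved, seq_nums=[1, 6, 11, 16, 21, 26, 31, 36])
        m = PairPotentialMatrix.default()
        types = ["ALA"] * 8
        s1 = _structure(pos, seq_nums=[1, 6, 11, 16, 21, 26, 31, 36], types=types)
        s2 = _structure(moved, seq_nums=[1, 6, 11, 16, 21, 26, 31, 36], types=types)
        pp1, pp2 = pair_potentials(s1, m), pair_potentials(s2, m)
        for a, b in zip(s1.ids(), s2.ids()):
            assert pp1[a] == pytest.approx(pp2[b], abs=1e-9)

    def test_default_matrix_is_symmetric(self):
        m = PairPotentialMatrix.default()
        for a in m.residue_types:
            for b in m.residue_types:
                assert m[(a, b)] == m[(b, a)]


class TestRelativeASA:
    @pytest.mark.parametrize(
        "asa,max_asa,expected", [(200.0, 200.0, 100.0), (0.0, 120.0, 0.0), (50.0, 200.0, 25.0)]
    )
    def test_values(self, asa, max_asa, expected):
        assert relative_complex_asa(asa, max_asa) == pytest.approx(expected)

    def test_nonpositive_max_asa_rejected(self):
        with pytest.raises(ValueError):
            relative_complex_asa(10.0, 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        asa=st.floats(0.0, 500.0),
        max_asa=st.floats(1.0, 400.0),
        scale=st.floats(0.1, 10.0),
    )
    def test_linear_in_asa_and_scale_inverse_in_max(self, asa, max_asa, scale):
        base = relative_complex_asa(asa, max_asa)
        assert relative_complex_asa(scale * asa, max_asa) == pytest.approx(scale * base)
        assert relative_complex_asa(asa, scale * max_asa) == pytest.approx(base / scale)

    def test_max_asa_table_covers_standard_residues(self):
        table = load_max_asa()
        assert len(table) == 20
        assert all(v > 0 for v in table.values())


class TestComputeASA:
    def test_single_glycine_matches_independent_integration(
        self, tmp_path, single_glycine_pdb_text
    ):
        """Rolling-probe ASA within 5% of an independent implementation."""
        p = tmp_path / "gly.pdb"
        p.write_text(single_glycine_pdb_text)
        ours = compute_asa(p, n_points=960)
        total = sum(ours.values())

        import biotite.structure.io.pdb as bpdb
        from biotite.structure import sasa

        arr = bpdb.PDBFile.read(str(p)).get_structure(model=1)
        ref = float(np.nansum(sasa(arr, probe_radius=1.4, point_number=2000)))
        assert total == pytest.approx(ref, rel=0.05)

    def test_buried_atom_contributes_zero(self, tmp_path, buried_atom_pdb_text):
        p = tmp_path / "buried.pdb"
        p.write_text(buried_atom_pdb_text)
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley

        model = next(PDBParser(QUIET=True).get_structure("b", str(p)).get_models())
        sr = ShrakeRupley(probe_radius=1.4, n_points=960)
        sr.compute(model, level="A")
        atoms = list(model.get_atoms())
        central = [a for a in atoms if a.get_name() == "C1"][0]
        assert central.sasa == 0.0

    def test_monomer_asa_not_below_complex_asa(self, tmp_path, glycine_dimer_pdb_text):
        p = tmp_path / "dimer.pdb"
        p.write_text(glycine_dimer_pdb_text)
        complex_asa = compute_asa(p)
        mono_a = compute_asa(p, chains=["A"])
        mono_b = compute_asa(p, chains=["B"])
        monomer = {**mono_a, **mono_b}
        assert set(monomer) == set(complex_asa)
        for rid in complex_asa:
            assert monomer[rid] >= complex_asa[rid] - 1e-9
        # the packed interface buries surface somewhere
        assert sum(monomer.values()) > sum(complex_asa.values())

    def test_ca_only_input_rejected(self, tmp_path, two_chain_pdb_text):
        p = tmp_path / "ca.pdb"
        p.write_text(two_chain_pdb_text)
        with pytest.raises(CaOnlyStructureError):
            compute_asa(p)


class TestPearsonRedundancyFilter:
    def test_identical_columns_second_dropped(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": x, "c": x % 2})  # |r(a, c)| ~ 0.17
        assert pearson_redundancy_filter(df, 0.9) == ["a", "c"]

    def test_anticorrelated_column_dropped(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": -x})
        assert pearson_redundancy_filter(df, 0.9) == ["a"]

    def test_independent_columns_retained(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
        r = abs(np.corrcoef(df["a"], df["b"])[0, 1])
        assert r < 0.9  # sanity on the fixture itself
        assert pearson_redundancy_filter(df, 0.9) == ["a", "b"]

    def test_constant_column_excluded_with_warning(self, caplog):
        df = pd.DataFrame({"a": np.arange(5.0), "b": np.ones(5)})
        with caplog.at_level("WARNING"):
            kept = pearson_redundancy_filter(df, 0.9)
        assert kept == ["a"]
        assert any("constant" in m for m in caplog.messages)
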