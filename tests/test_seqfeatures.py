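"""Reference mapping, shell selection and feature-matrix construction checks."""

import numpy as np
import pandas as pd
import pytest

from fdmoscreen import synthetic as syn
from fdmoscreen.errors import DomainError, LookupError_
from fdmoscreen.seqfeatures import (
    Alignment,
    ResidueSet,
    build_feature_matrix,
    map_reference_numbering,
    read_alignment,
    residues_of_interest_union,
    select_binding_site_residues,
    select_second_shell,
    stereo_labels_from_calls,
    translate_residue_numbers,
    write_alignment,
)
from fdmoscreen.structio import AtomRecord, ComplexStructure, Pose


class TestReferenceMap:
    def test_gapped_reference_counts_non_gaps(self):
        aln = Alignment(ids=["ref", "x"], rows=["A-CD", "AACD"])
        m = map_reference_numbering(aln, "ref")
        assert m.col_to_res == {1: 1, 3: 2, 4: 3}
        assert m.residue_for_column(2) is None

    def test_gapless_reference_is_identity(self):
        aln = Alignment(ids=["ref"], rows=["ACDEF"])
        m = map_reference_numbering(aln, "ref")
        assert m.col_to_res == {i: i for i in range(1, 6)}

    def test_all_gap_reference_warns_empty(self):
        aln = Alignment(ids=["ref", "x"], rows=["---", "ACD"])
        with pytest.warns(UserWarning):
            m = map_reference_numbering(aln, "ref")
        assert m.col_to_res == {}

    def test_missing_reference_id(self):
        aln = Alignment(ids=["a"], rows=["ACD"])
        with pytest.raises(LookupError_):
            map_reference_numbering(aln, "ref")

    def test_round_trip_column_residue_column(self):
        aln = Alignment(ids=["ref"], rows=["AC-DE-FG"])
        m = map_reference_numbering(aln, "ref")
        for col, res in m.col_to_res.items():
            assert m.column_for_residue(res) == col

    def test_fasta_io_round_trip(self, tmp_path):
        aln = Alignment(ids=["ref", "x"], rows=["A-CD", "AACD"])
        p = tmp_path / "aln.fasta"
        write_alignment(aln, p)
        back = read_alignment(p)
        assert back.ids == aln.ids and back.rows == aln.rows


def _receptor(residue_positions):
    """One CA atom per residue at the given positions, plus an FAD atom."""
    atoms = [AtomRecord("CA", "C", i + 1, "ALA", "A", np.asarray(p, dtype=float))
             for i, p in enumerate(residue_positions)]
    fad = [AtomRecord("C4A", "C", 900, "FAD", "F", np.array([50.0, 50.0, 50.0]))]
    return ComplexStructure(protein_atoms=atoms, fad_atoms=fad)


def _pose(points, pose_id=1):
    atoms = [AtomRecord(f"C{i + 1}", "C", 1, "LIG", "X", np.asarray(p, dtype=float))
             for i, p in enumerate(points)]
    return Pose(pose_id=pose_id, ligand_atoms=atoms, energy=-1.0)


class TestShellSelection:
    def test_inclusive_cutoff_boundaries(self):
        receptor = _receptor([(4.4, 0, 0), (4.6, 0, 0), (20, 0, 0)])
        pose = _pose([(0, 0, 0), (0, 1, 0), (0, 0, 1)])
        bs = select_binding_site_residues(receptor, [pose], cutoff=4.5)
        assert 1 in bs and 2 not in bs and 3 not in bs

    def test_union_over_ligand_poses(self):
        receptor = _receptor([(4.0, 0, 0), (104.0, 0, 0)])
        near_origin = _pose([(0, 0, 0), (0, 1, 0), (0, 0, 1)])
        near_far = _pose([(100, 0, 0), (100, 1, 0), (100, 0, 1)], pose_id=2)
        bs = select_binding_site_residues(receptor, [near_origin, near_far])
        assert bs.residues == frozenset({1, 2})

    def test_empty_pose_list_rejected(self):
        with pytest.raises(DomainError):
            select_binding_site_residues(_receptor([(0, 0, 0)]), [])

    def test_second_shell_excludes_binding_site(self):
        receptor = _receptor([(3.0, 0, 0), (6.0, 0, 0), (30.0, 0, 0)])
        pose = _pose([(0, 0, 0), (0, 1, 0), (0, 0, 1)])
        bs = select_binding_site_residues(receptor, [pose])
        shell = select_second_shell(receptor, bs)
        assert bs.residues == frozenset({1})
        assert shell.residues == frozenset({2})  # 3 A from residue 1; residue 3 remote

    def test_second_shell_needs_nonempty_binding_site(self):
        with pytest.raises(DomainError):
            select_second_shell(_receptor([(0, 0, 0)]), ResidueSet(frozenset()))

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        receptor = _receptor(rng.uniform(-8, 8, size=(30, 3)))
        pose = _pose([(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        small = select_binding_site_residues(receptor, [pose], cutoff=4.5)
        large = select_binding_site_residues(receptor, [pose], cutoff=5.0)
        assert small.residues <= large.residues

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(8)
        positions = rng.uniform(-10, 10, size=(40, 3))
        receptor = _receptor(positions)
        pts = rng.uniform(-3, 3, size=(5, 3))
        pose = _pose(pts)
        bs = select_binding_site_residues(receptor, [pose], cutoff=4.5)
        expected = {
            i + 1
            for i, p in enumerate(positions)
            if min(np.linalg.norm(p - q) for q in pts) <= 4.5
        }
        assert bs.residues == frozenset(expected)


class TestResidueTranslation:
    def test_translation_through_alignment(self):
        aln = Alignment(ids=["TropB", "other"], rows=["AC-DE", "-CFDE"])
        # TropB res 2 ('C', col 2) -> other res 1; TropB res 3 ('D', col 4) -> other res 3
        out = translate_residue_numbers(aln, "TropB", "other", ResidueSet(frozenset({2, 3})))
        assert out.residues == frozenset({1, 3})

    def test_union(self):
        a = ResidueSet(frozenset({1, 2}))
        b = ResidueSet(frozenset({2, 3}))
        assert residues_of_interest_union([a, b]).residues == frozenset({1, 2, 3})
        assert residues_of_interest_union([a, a]).residues == a.residues

    def test_union_of_nothing_warns_empty(self):
        with pytest.warns(UserWarning):
            assert len(residues_of_interest_union([])) == 0


class TestFeatureMatrix:
    def _alignment(self, n_rows=100, gap_rows_col2=12):
        rows = []
        for i in range(n_rows):
            c1 = "A"
            c2 = "-" if i < gap_rows_col2 else "W"
            c3 = "F" if i % 2 == 0 else "Y"
            rows.append(c1 + c2 + c3)
        return Alignment(ids=[f"s{i}" for i in range(n_rows)], rows=rows)

    def _labels(self, ids):
        return pd.DataFrame(
            {"stereochemistry": [1] * (len(ids) // 2) + [-1] * (len(ids) - len(ids) // 2),
             "reactivity": [1, 0] * (len(ids) // 2)},
            index=ids,
        )

    def test_gappy_column_dropped_strictly_above_threshold(self):
        aln = self._alignment(gap_rows_col2=12)  # 12% gaps
        refmap = map_reference_numbering(
            Alignment(ids=["r"], rows=["AAA"]), "r"
        )
        roi = ResidueSet(frozenset({1, 2, 3}))
        fm = build_feature_matrix(aln, roi, refmap, self._labels(aln.ids))
        assert fm.residues == [1, 3] and 2 in fm.dropped_columns

    def test_exactly_at_threshold_retained(self):
        aln = self._alignment(gap_rows_col2=10)  # exactly 10%
        refmap = map_reference_numbering(Alignment(ids=["r"], rows=["AAA"]), "r")
        fm = build_feature_matrix(aln, ResidueSet(frozenset({1, 2, 3})), refmap,
                                  self._labels(aln.ids))
        assert fm.residues == [1, 2, 3]

    def test_column_outside_roi_dropped(self):
        aln = self._alignment(gap_rows_col2=0)
        refmap = map_reference_numbering(Alignment(ids=["r"], rows=["AAA"]), "r")
        fm = build_feature_matrix(aln, ResidueSet(frozenset({1, 3})), refmap,
                                  self._labels(aln.ids))
        assert fm.residues == [1, 3]

    def test_gap_is_its_own_category_in_encoding(self):
        aln = self._alignment(gap_rows_col2=5)
        refmap = map_reference_numbering(Alignment(ids=["r"], rows=["AAA"]), "r")
        fm = build_feature_matrix(aln, ResidueSet(frozenset({2})), refmap,
                                  self._labels(aln.ids))
        enc = fm.encoded()
        assert enc[0, 0] == 0  # gap category is code 0
        assert len(np.unique(enc[:, 0])) == 2

    def test_bad_labels_rejected(self):
        aln = self._alignment()
        refmap = map_reference_numbering(Alignment(ids=["r"], rows=["AAA"]), "r")
        labels = self._labels(aln.ids)
        labels.loc[labels.index[0], "stereochemistry"] = 2
        with pytest.raises(DomainError):
            build_feature_matrix(aln, ResidueSet(frozenset({1})), refmap, labels)

    def test_unmapped_roi_column_rejected(self):
        aln = self._alignment()
        refmap = map_reference_numbering(Alignment(ids=["r"], rows=["AAA"]), "r")
        with pytest.raises(LookupError_):
            build_feature_matrix(aln, ResidueSet(frozenset({9})), refmap,
                                 self._labels(aln.ids))


class TestStereoLabelConsensus:
    def test_mode_consensus(self):
        calls = pd.DataFrame(
            {"lig2": ["R", "R", "S"], "lig3": ["R", "S", "S"],
             "lig4": ["S", "R", "R/S"], "lig5": ["R", "S", "S"]},
            index=["e1", "e2", "e3"],
        )
        out = stereo_labels_from_calls(calls, method="mode")
        assert out.tolist() == [1, 0, -1]  # e2 ties R vs S -> racemic 0

    def test_mean_consensus_with_racemic_band(self):
        calls = pd.DataFrame(
            {"lig2": ["R", "R"], "lig3": ["R", "S"], "lig4": ["R", "S"], "lig5": ["S", "R"]},
            index=["e1", "e2"],
        )
        out = stereo_labels_from_calls(calls, method="mean")
        assert out.tolist() == [1, 0]  # e1 mean 0.5 -> R; e2 mean 0 -> racemic


def test_screen_matrix_columns_follow_generator(small_screen):
    features, truth = small_screen
    assert truth["stereo_switch_column"] in features.residues
    col = features.data[truth["stereo_switch_column"]]
    assert set(col.unique()) <= set(truth["stereo_alleles"])
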