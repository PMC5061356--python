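import pytest
from hypothesis import given, strategies as st

from cbcdelim.errors import ProjectionError, StructureError
from cbcdelim.io import Alignment
from cbcdelim.refmodels import synthetic_its1_model, synthetic_its2_model
from cbcdelim.structure import (SecondaryStructure, consensus_fold,
                                decompose_helices, detect_structure_deletions,
                                pairs_from_dotbracket, project_to_alignment)

from tests.oracles import best_fold_bruteforce


class TestDotBracket:
    def test_stack_matched_pairs(self):
        s = pairs_from_dotbracket("(((...)))")
        assert s.pairs == {(1, 9), (2, 8), (3, 7)}

    def test_all_dots_no_pairs(self):
        assert pairs_from_dotbracket(".........").pairs == frozenset()

    def test_short_hairpin_loop_rejected(self):
        with pytest.raises(StructureError):
            pairs_from_dotbracket("((..))")

    def test_unbalanced_open_rejected(self):
        with pytest.raises(StructureError):
            pairs_from_dotbracket("((...)")

    def test_round_trip(self):
        db = "((((...)))).((...))."
        assert pairs_from_dotbracket(db).to_dotbracket() == db


class TestSecondaryStructureInvariants:
    def test_crossing_pairs_rejected(self):
        with pytest.raises(StructureError):
            SecondaryStructure(length=12, pairs={(1, 8), (4, 12)})

    def test_position_in_two_pairs_rejected(self):
        with pytest.raises(StructureError):
            SecondaryStructure(length=12, pairs={(1, 8), (8, 12)})


class TestDecomposeHelices:
    def test_two_arm_toy(self):
        s = pairs_from_dotbracket("(((...)))...((...))")
        arms = decompose_helices(s)
        assert [(a.label, a.start, a.end) for a in arms] == \
            [("I", 1, 9), ("II", 13, 19)]

    def test_pairs_partitioned_across_arms(self):
        _, s = synthetic_its1_model()
        arms = decompose_helices(s)
        total = sum(a.n_pairs for a in arms)
        assert total == len(s.pairs)
        assert frozenset().union(*(a.pairs for a in arms)) == s.pairs

    def test_no_pairs_yields_no_arms(self):
        assert decompose_helices(SecondaryStructure(length=8)) == []

    def test_its1_model_has_five_helices(self):
        _, s = synthetic_its1_model()
        assert [a.label for a in decompose_helices(s)] == ["I", "II", "III", "IV", "V"]

    def test_its2_model_helix_spans(self):
        _, s = synthetic_its2_model()
        arms = {a.label: a for a in decompose_helices(s)}
        assert arms["II"].n_nt == 32
        assert arms["III"].n_nt == 67


class TestProjection:
    def test_gap_shift(self):
        aln = Alignment([("tmpl", "GG-GAAACCC"), ("o", "GGAGAAACCC")])
        pcm = project_to_alignment(aln, "tmpl", pairs_from_dotbracket("(((...)))"),
                                   "ITS1")
        assert pcm.paired_cols == ((1, 10), (2, 9), (4, 8))

    def test_gap_free_template_is_identity(self):
        aln = Alignment([("tmpl", "GGGAAACCC"), ("o", "GGGAAACCC")])
        s = pairs_from_dotbracket("(((...)))")
        pcm = project_to_alignment(aln, "tmpl", s, "ITS1")
        assert pcm.paired_cols == tuple(sorted(s.pairs))
        assert pcm.unpaired_cols == (4, 5, 6)

    def test_inserted_column_elsewhere_does_not_move_map(self):
        s = pairs_from_dotbracket("(((...)))")
        plain = project_to_alignment(
            Alignment([("tmpl", "GG-GAAACCC"), ("o", "GGAGAAACCC")]),
            "tmpl", s, "ITS1")
        threeseq = project_to_alignment(
            Alignment([("tmpl", "GG-GAAACCC"), ("o", "GGAGAAACCC"),
                       ("p", "GG-GAAACCC")]),
            "tmpl", s, "ITS1")
        assert plain.paired_cols == threeseq.paired_cols

    def test_unproject_round_trip(self):
        _, s = synthetic_its2_model()
        rec, _ = synthetic_its2_model()
        gapped = rec.residues[:50] + "--" + rec.residues[50:]
        other = gapped.replace("-", "A")
        aln = Alignment([("tmpl", gapped), ("o", other)])
        pcm = project_to_alignment(aln, "tmpl", s, "ITS2")
        assert pcm.unproject().pairs == s.pairs

    def test_length_mismatch_rejected(self):
        aln = Alignment([("tmpl", "GGGAAACC"), ("o", "GGGAAACC")])
        with pytest.raises(ProjectionError):
            project_to_alignment(aln, "tmpl", pairs_from_dotbracket("(((...)))"),
                                 "ITS1")

    def test_missing_template_id_rejected(self):
        aln = Alignment([("a", "GGGAAACCC"), ("b", "GGGAAACCC")])
        with pytest.raises(ProjectionError):
            project_to_alignment(aln, "zz", pairs_from_dotbracket("(((...)))"),
                                 "ITS1")


class TestConsensusFold:
    def test_single_row_maximal_pairing(self):
        assert consensus_fold("GGGAAACCC").to_dotbracket() == "(((...)))"

    def test_all_a_alignment_is_unpaired(self):
        aln = Alignment([("a", "AAAAAAAA"), ("b", "AAAAAAAA")])
        assert consensus_fold(aln).pairs == frozenset()

    def test_compensatory_columns_kept_with_bonus(self):
        rows = ["GCGAAACGC", "AUGAAACAU"]
        aln = Alignment([("a", rows[0]), ("b", rows[1])])
        got = consensus_fold(aln)
        expected, _ = best_fold_bruteforce(rows)
        assert got.pairs == expected
        # the two covarying outer pairs are present
        assert {(1, 9), (2, 8)} <= got.pairs

    def test_threshold_blocks_sparse_pairing(self):
        # only one of four rows can pair the ends: below the 0.5 threshold
        aln = Alignment([("a", "GAAAAAC"), ("b", "AAAAAAA"),
                         ("c", "AAAAAAA"), ("d", "AAAAAAA")])
        assert consensus_fold(aln).pairs == frozenset()


class TestStructureDeletions:
    def test_gap_free_taxon_has_no_losses(self, hairpin_map):
        aln = Alignment([("t1", "GGGAAACCC"), ("t2", "GGGAAACCC")])
        assert detect_structure_deletions(hairpin_map, aln) == {"t1": [], "t2": []}

    def test_single_column_gap_loses_one_pair(self, hairpin_map):
        aln = Alignment([("t1", "GGGAAACCC"), ("t2", "GG-AAACCC")])
        out = detect_structure_deletions(hairpin_map, aln)
        assert out["t2"] == [("I", 1, [(3, 7)])]

    def test_both_column_gaps_counted_once_per_pair(self, hairpin_map):
        aln = Alignment([("t1", "GGGAAACCC"), ("t2", "--GAAACC-")])
        out = detect_structure_deletions(hairpin_map, aln)
        (label, n, pairs), = out["t2"]
        assert (label, n) == ("I", 2) and set(pairs) == {(1, 9), (2, 8)}


@given(st.integers(0, 10_000))
def test_fold_respects_structure_invariants(seed):
    """Any folded structure validates: nesting, disjoint positions, loop >= 3."""
    import numpy as np
    rng = np.random.default_rng(seed)
    seq = "".join("ACGU"[k] for k in rng.integers(0, 4, size=rng.integers(4, 15)))
    s = consensus_fold(seq)  # SecondaryStructure __post_init__ enforces invariants
    assert all(j - i - 1 >= 3 for i, j in s.pairs)
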