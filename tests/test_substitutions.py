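from itertools import product

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cbcdelim.errors import AlphabetError, ValidationError
from cbcdelim.io import Alignment
from cbcdelim.substitutions import (CBC, HCBC, INDEL, NONCBC, OTHER_PAIRED,
                                    SINGLE, CbcMatrix, PairState, cbc_matrix,
                                    classify_pair_state, classify_transition,
                                    count_site_patterns, enumerate_site_events,
                                    transition_subtype)

pair_states = st.tuples(st.sampled_from("ACGU"), st.sampled_from("ACGU")) \
    .map(lambda t: PairState(*t))


class TestPairState:
    @pytest.mark.parametrize("x,y,klass", [
        ("C", "G", "canonical"), ("A", "U", "canonical"),
        ("G", "U", "wobble"), ("U", "G", "wobble"),
        ("A", "C", "noncanonical"), ("G", "G", "noncanonical"),
        ("-", "G", "incomplete"), ("A", "N", "incomplete"),
    ])
    def test_classification(self, x, y, klass):
        assert classify_pair_state(x, y).klass == klass

    def test_bad_character_rejected(self):
        with pytest.raises(AlphabetError):
            classify_pair_state("X", "G")


class TestClassifyTransition:
    @pytest.mark.parametrize("a,b,cat", [
        ("CG", "UA", CBC),          # double-sided, canonical to canonical
        ("GC", "GU", HCBC),         # one-sided canonical -> wobble
        ("GC", "AC", NONCBC),       # stem-breaking change
        ("GU", "GC", HCBC),         # symmetric direction
        ("GC", "UG", OTHER_PAIRED),  # both strands change, canonical<->wobble
        ("GU", "UG", OTHER_PAIRED),  # wobble<->wobble
        ("AC", "AG", OTHER_PAIRED),  # noncanonical<->noncanonical
    ])
    def test_categories(self, a, b, cat):
        assert classify_transition(PairState(*a), PairState(*b)) == cat

    def test_identical_states_are_no_event(self):
        assert classify_transition(PairState("G", "C"), PairState("G", "C")) is None

    def test_incomplete_state_is_contract_violation(self):
        with pytest.raises(ValidationError):
            classify_transition(PairState("-", "C"), PairState("G", "C"))

    @given(pair_states, pair_states)
    def test_symmetric(self, p, q):
        assert classify_transition(p, q) == classify_transition(q, p)

    def test_other_paired_subtypes(self):
        assert transition_subtype(PairState("G", "C"), PairState("U", "G")) == \
            "double_sided_canonical_wobble"
        assert transition_subtype(PairState("G", "U"), PairState("U", "G")) == \
            "wobble_wobble"
        assert transition_subtype(PairState("C", "G"), PairState("U", "A")) is None


class TestEnumerateSiteEvents:
    def test_two_state_paired_site_is_one_cbc(self, hairpin_map):
        aln = Alignment([("t1", "CGGAAACCG"), ("t2", "CGGAAACCG"),
                         ("t3", "UGGAAACCA")])
        events = [e for e in enumerate_site_events(aln, hairpin_map)
                  if e.category == CBC]
        assert len(events) == 1
        ev = events[0]
        assert ev.site == (1, 9)
        assert {frozenset({"t1", "t2"}), frozenset({"t3"})} == set(ev.between)

    def test_gc_gu_site_is_one_hcbc(self, hairpin_map):
        aln = Alignment([("t1", "GGGAAACCC"), ("t2", "GGGAAACCU")])
        cats = [e.category for e in enumerate_site_events(aln, hairpin_map)]
        assert cats.count(HCBC) == 1 and CBC not in cats

    def test_unpaired_column_variation_is_single(self, hairpin_map):
        aln = Alignment([("t1", "GGGAAACCC"), ("t2", "GGGACACCC")])
        evs = enumerate_site_events(aln, hairpin_map)
        assert [(e.category, e.site) for e in evs] == [(SINGLE, (5,))]

    def test_gap_state_emits_indel_not_substitution(self, hairpin_map):
        aln = Alignment([("t1", "GGGAAACCC"), ("t2", "-GGAAACC-")])
        evs = enumerate_site_events(aln, hairpin_map)
        assert {e.category for e in evs} == {INDEL}
        assert sum(1 for e in evs if e.site == (1, 9)) == 1

    def test_n_sites_excluded_and_reported(self, hairpin_map):
        aln = Alignment([("t1", "GGGAAACCC"), ("t2", "NGGAAACCC")])
        evs, excluded = enumerate_site_events(aln, hairpin_map,
                                              return_excluded=True)
        assert (1, 9) in excluded and not evs

    @given(st.integers(0, 500))
    def test_events_per_site_follow_pair_count(self, seed):
        """A site showing s distinct complete states emits s*(s-1)/2 events."""
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(2, 7))
        rows = []
        for t in range(n_taxa):
            x, y = rng.choice(list("ACGU"), size=2)
            rows.append((f"t{t}", x + "AAA" + y))
        aln = Alignment(rows)
        from cbcdelim.structure import PairedColumnMap
        pcm = PairedColumnMap(region_label="ITS1", template_id="t0",
                              paired_cols=((1, 5),), unpaired_cols=(),
                              helix_of_pair={(1, 5): "I"},
                              col_of_pos={1: 1, 2: 5})
        s = len({r[1][0] + r[1][4] for r in rows})
        evs = enumerate_site_events(aln, pcm)
        assert len(evs) == s * (s - 1) // 2


class TestCbcMatrix:
    def test_one_cbc_splits_two_vs_two(self, hairpin_map):
        aln = Alignment([("a", "CGGAAACCG"), ("b", "CGGAAACCG"),
                         ("c", "UGGAAACCA"), ("d", "UGGAAACCA")])
        m = cbc_matrix(aln, [hairpin_map])
        for x in "ab":
            for y in "cd":
                assert m.count(x, y) == 1
        assert m.count("a", "b") == 0 and m.count("c", "d") == 0

    def test_identical_rows_give_zero_matrix(self, hairpin_map):
        aln = Alignment([("a", "GGGAAACCC"), ("b", "GGGAAACCC")])
        assert not cbc_matrix(aln, [hairpin_map]).counts.any()

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            CbcMatrix(taxa=["a", "b"], counts=np.array([[0, 1], [0, 0]]))


class TestSitePatterns:
    def test_distinct_columns(self):
        aln = Alignment([("a", "AC"), ("b", "AC"), ("c", "GC")])
        assert count_site_patterns(aln) == 2

    def test_monomorphic_alignment_has_one_pattern(self):
        aln = Alignment([("a", "AAAA"), ("b", "AAAA")])
        assert count_site_patterns(aln) == 1

    def test_gap_is_a_fifth_state(self):
        aln = Alignment([("a", "A-"), ("b", "AA")])
        assert count_site_patterns(aln) == 2
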