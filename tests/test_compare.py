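"""Repertoire mapping, motif edits, positional chance models, G-test,
total deviation, and branch-point comparison."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import songseq as s
from conftest import corpus_of

LABEL_SETS = st.sets(st.sampled_from("abcdefghij"), min_size=0, max_size=8)


class TestRepertoireMap:
    def test_thirteen_to_ten(self):
        tutor = corpus_of(" ".join(chr(97 + i) for i in range(13)))
        pupil = corpus_of(" ".join(chr(97 + i) for i in range(10)) + " x y")
        rep = s.map_repertoire(tutor, pupil)
        assert len(rep.retained) == 10
        assert rep.pct_retained_of_tutor == pytest.approx(76.9, abs=0.05)
        assert round(rep.pct_retained_of_tutor) == 77

    def test_identical_and_disjoint(self):
        a, b = corpus_of("a b c"), corpus_of("x y")
        same = s.map_repertoire(a, a)
        assert same.pct_retained_of_tutor == 100.0
        assert same.novel == set()
        diff = s.map_repertoire(a, b)
        assert diff.pct_retained_of_tutor == 0.0
        assert diff.pct_novel_of_pupil == 100.0

    def test_label_map_conflict_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            s.map_repertoire(corpus_of("a b"), corpus_of("p q"),
                             label_map={"p": "a", "q": "a"})

    @settings(max_examples=100, deadline=None)
    @given(tutor=LABEL_SETS, pupil=LABEL_SETS)
    def test_partition_identities(self, tutor, pupil):
        if not tutor or not pupil:
            return
        t = s.SongCorpus.from_label_lists("t", [sorted(tutor)])
        p = s.SongCorpus.from_label_lists("p", [sorted(pupil)])
        rep = s.map_repertoire(t, p)
        assert rep.retained | rep.dropped == tutor
        assert rep.retained | rep.novel == pupil
        assert not (rep.retained & rep.dropped)
        assert not (rep.retained & rep.novel)
        assert not (rep.dropped & rep.novel)


class TestPrevalenceByRetention:
    def test_group_means(self):
        r = s.prevalence_by_retention({"a": 0.4, "b": 0.1}, {"a"}, {"b"})
        assert (r["mean_retained"], r["mean_dropped"]) == (0.4, 0.1)

    def test_empty_class_signals_exclusion(self):
        with pytest.raises(s.PairExcludedError, match="pair excluded"):
            s.prevalence_by_retention({"a": 0.4, "b": 0.6}, {"a", "b"}, set())


class TestScoreMotifEdits:
    # the five canonical worked examples
    @pytest.mark.parametrize("tutor,pupil,expected", [
        ("abcd", "rtbcd", [("deletion", "beginning", "a"),
                           ("addition", "beginning", "r"),
                           ("addition", "beginning", "t")]),
        ("abcd", "abcef", [("deletion", "end", "d"),
                           ("addition", "end", "e"),
                           ("addition", "end", "f")]),
        ("abcd", "abq", [("deletion", "middle", "c"),
                         ("deletion", "end", "d"),
                         ("addition", "end", "q")]),
        ("abc", "rabc", [("addition", "beginning", "r")]),
        ("abcd", "abd", [("deletion", "middle", "c")]),
    ])
    def test_worked_examples(self, tutor, pupil, expected):
        edits = s.score_motif_edits(tuple(tutor), tuple(pupil))
        got = sorted((e.type, e.position, e.label) for e in edits)
        assert got == sorted(expected)

    def test_identical_motifs_have_no_edits(self):
        assert s.score_motif_edits(("a", "b"), ("a", "b")) == []

    def test_disjoint_motifs_not_comparable(self):
        with pytest.raises(ValueError, match="not comparable"):
            s.score_motif_edits(("a", "b"), ("x", "y"))

    def test_shuffle_scored_as_paired_edits(self):
        # "rtg" vs "etr": r and t swapped order; one syllable carries the
        # backbone and the shuffle appears as paired addition + deletion
        edits = s.score_motif_edits(("r", "t", "g"), ("e", "t", "r"))
        types = {e.type for e in edits}
        assert types == {"addition", "deletion"}

    def test_per_instance_counting_collapses_blocks(self):
        edits = s.score_motif_edits(("a", "b", "c", "d"),
                                    ("a", "b", "c", "e", "f"))
        per_syll = s.count_edit_positions(edits, "addition")
        per_inst = s.count_edit_positions(edits, "addition",
                                          per_instance=True)
        assert per_syll == (0, 0, 2)
        assert per_inst == (0, 0, 1)


class TestClassifyMotif:
    def _m(self, labels, prev=0.5):
        return s.Motif(labels=tuple(labels), count=10,
                       relative_prevalence=prev)

    def test_matched(self):
        c = s.classify_motif(self._m("abcd"), [self._m("abcd")])
        assert c.status == "matched" and c.edits == []

    def test_modified_at_three_quarters_shared(self):
        c = s.classify_motif(self._m("abcd"), [self._m("rtbcd")])
        assert c.status == "modified"
        assert c.shared_fraction == pytest.approx(0.75)
        assert c.edits

    def test_dropped_below_half(self):
        c = s.classify_motif(self._m("abcd"), [self._m("axyz"[0] + "xyz")])
        assert c.status == "dropped"

    def test_half_is_retained_inclusive(self):
        c = s.classify_motif(self._m("ab"), [self._m("axy")])
        assert c.shared_fraction == 0.5
        assert c.status == "modified"

    def test_one_to_one_matching(self):
        comps = s.match_motifs([self._m("abcd"), self._m("abce")],
                               [self._m("abcd")])
        statuses = {tuple(c.tutor_motif.labels): c.status for c in comps}
        assert statuses[("a", "b", "c", "d")] == "matched"
        assert statuses[("a", "b", "c", "e")] == "dropped"


class TestPositionChanceModel:
    def test_two_syllable_motif_has_no_middle(self):
        assert s.position_chance_model([2], "deletion") == (0.5, 0.0, 0.5)

    def test_pooled_slots(self):
        assert s.position_chance_model([4, 4], "deletion") == \
            pytest.approx((0.25, 0.5, 0.25))
        dele = s.position_chance_model([2, 3, 4, 5], "deletion")
        assert dele == pytest.approx((4 / 14, 6 / 14, 4 / 14))
        add = s.position_chance_model([2, 3, 4, 5], "addition")
        assert add == pytest.approx((4 / 18, 10 / 18, 4 / 18))
        # the same multisets printed as percentages: 29/43/29 and 22/55/22
        assert [round(100 * p) for p in dele] == [29, 43, 29]
        assert [round(100 * p) for p in add] == [22, 56, 22]

    @settings(max_examples=50, deadline=None)
    @given(lengths=st.lists(st.integers(2, 7), min_size=1, max_size=10))
    def test_matches_explicit_slot_enumeration(self, lengths):
        for edit_type in ("addition", "deletion"):
            # oracle: write out every slot and classify it
            slots = []
            for L in lengths:
                if edit_type == "deletion":
                    slots += (["beginning"] + ["middle"] * (L - 2) + ["end"])
                else:
                    slots += (["beginning"] + ["middle"] * (L - 1) + ["end"])
            expect = tuple(slots.count(p) / len(slots)
                           for p in ("beginning", "middle", "end"))
            got = s.position_chance_model(lengths, edit_type)
            assert got == pytest.approx(expect)
            assert sum(got) == pytest.approx(1.0)


class TestExpectedCountsAndGTest:
    def test_expected_deletion_counts(self):
        probs = s.position_chance_model([2, 3, 4, 5], "deletion")
        exp = s.expected_edit_counts(24, probs)
        assert [round(e) for e in exp] == [7, 10, 7]

    def test_expected_addition_counts(self):
        exp = s.expected_edit_counts(29, (2 / 9, 5 / 9, 2 / 9))
        assert exp == pytest.approx((6.444, 16.111, 6.444), abs=1e-3)

    def test_zero_edits(self):
        assert s.expected_edit_counts(0, (0.25, 0.5, 0.25)) == (0, 0, 0)

    def test_null_gives_zero_statistic(self):
        res = s.g_test((10, 20, 10), (0.25, 0.5, 0.25))
        assert res["G"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_evaluated_statistics(self):
        res = s.g_test((16, 3, 10), (2 / 9, 5 / 9, 2 / 9))
        assert res["G"] == pytest.approx(27.81, abs=0.01)
        assert res["df"] == 2
        res2 = s.g_test((8, 12, 4), (2 / 7, 3 / 7, 2 / 7))
        assert res2["G"] == pytest.approx(1.854, abs=0.001)
        assert res2["p"] == pytest.approx(0.396, abs=0.001)

    def test_zero_expected_with_observed_rejected(self):
        with pytest.raises(ValueError):
            s.g_test((5, 5, 5), (0.5, 0.5, 0.0))


class TestTotalDeviation:
    def test_printed_bounds(self):
        d = {"a": 0.91, "w": 0.04, "q": 0.03, "m": 0.02}
        assert s.total_deviation(d, d) == 0.0
        assert s.total_deviation({"x": 1.0}, {"y": 1.0}) == 200.0

    def test_worked_example_value(self):
        tutor = {"a": 0.91, "w": 0.04, "q": 0.03, "m": 0.02}
        pupil = {"a": 0.96, "w": 0.02, "q": 0.02}
        assert s.total_deviation(tutor, pupil) == pytest.approx(10.0)

    def test_normalization_enforced(self):
        with pytest.raises(ValueError):
            s.total_deviation({"a": 0.7}, {"a": 1.0})

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_scaled_l1_metric_properties(self, data):
        labels = ["a", "b", "c", "d"]

        def dist():
            w = data.draw(st.lists(st.floats(0.01, 1.0), min_size=4,
                                   max_size=4))
            tot = sum(w)
            return dict(zip(labels, (x / tot for x in w)))

        d1, d2, d3 = dist(), dist(), dist()
        t12 = s.total_deviation(d1, d2)
        assert t12 == pytest.approx(s.total_deviation(d2, d1))
        assert 0 <= t12 <= 200
        assert s.total_deviation(d1, d1) == pytest.approx(0.0, abs=1e-9)
        assert t12 <= s.total_deviation(d1, d3) + \
            s.total_deviation(d3, d2) + 1e-9


class TestCompareBranchPoint:
    def _bp(self, labels, transitions, n=100):
        motif = s.Motif(labels=tuple(labels), count=n,
                        relative_prevalence=1.0)
        return s.BranchPoint(motif, transitions, n)

    def _comp(self, tutor_labels, pupil_labels, status="matched"):
        tm = s.Motif(labels=tuple(tutor_labels), count=10,
                     relative_prevalence=1.0)
        pm = s.Motif(labels=tuple(pupil_labels), count=10,
                     relative_prevalence=1.0)
        return s.MotifComparison(status, tm, pm, 1.0, [])

    def test_retained_with_dropped_transition(self):
        """'rtg' -> a/w/q/m at 91/4/3/2; pupil keeps a, w, q only."""
        tutor_bp = self._bp("rtg", {"a": 0.91, "w": 0.04, "q": 0.03,
                                    "m": 0.02})
        pupil_bp = self._bp("rtg", {"a": 0.96, "w": 0.02, "q": 0.02})
        comp = s.compare_branch_point(tutor_bp, [self._comp("rtg", "rtg")],
                                      [pupil_bp])
        assert comp.status == "retained"
        assert comp.dropped_transitions == {"m"}
        assert comp.retained_transitions == {"a", "w", "q"}
        assert comp.dominant_match is True
        assert comp.total_deviation_pct == pytest.approx(10.0)

    def test_stereotyped_in_pupil(self):
        tutor_bp = self._bp("ab", {"x": 0.7, "y": 0.3})
        pupil_motif = s.Motif(labels=("a", "b"), count=10,
                              relative_prevalence=1.0)
        comp = s.compare_branch_point(
            tutor_bp, [self._comp("ab", "ab")], [],
            pupil_stereotyped=[(pupil_motif, "x")])
        assert comp.status == "dropped_stereotyped_in_pupil"
        assert comp.dominant_match is True

    def test_identical_pupil(self):
        tutor_bp = self._bp("ab", {"x": 0.6, "y": 0.4})
        comp = s.compare_branch_point(tutor_bp, [self._comp("ab", "ab")],
                                      [tutor_bp])
        assert comp.status == "retained"
        assert comp.total_deviation_pct == 0.0
        assert comp.entropy_tutor == comp.entropy_pupil

    def test_dropped_sequence(self):
        tutor_bp = self._bp("ab", {"x": 0.6, "y": 0.4})
        comp = s.compare_branch_point(tutor_bp, [], [])
        assert comp.status == "dropped_sequence"
        assert comp.dropped_transitions == {"x", "y"}


class TestEndToEndEditRecovery:
    def test_injected_edits_recovered(self):
        """Single-syllable edits injected by the learning model are
        recovered by score_motif_edits with matching type and position."""
        params = s.LearningParams(retention_intercept=50, retention_slope=0,
                                  edit_rate=1.0, novel_syllable_rate=0.5)
        total = correct = 0
        for seed in range(100):
            g = s.sample_tutor_grammar(
                s.GrammarConfig(with_features=False, with_gaps=False),
                seed=seed)
            pupil, log = s.derive_pupil(g, params, seed=5000 + seed)
            for mid, injected in log.motif_edits.items():
                tutor_labels = g.motif_by_id(mid).labels
                recovered = s.score_motif_edits(
                    tutor_labels, log.pupil_motif_labels[mid])
                got = sorted((e.type, e.position, e.label)
                             for e in recovered)
                want = sorted((e.type, e.position, e.label)
                              for e in injected)
                total += 1
                correct += got == want
        assert total > 100
        assert correct / total >= 0.95
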