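"""The synthetic song model: tutor sampling, pupil derivation, corpora."""

from __future__ import annotations

import math

import numpy as np
import pytest

import songseq as s


def rows_close(g1: s.Grammar, g2: s.Grammar, tol=1e-9) -> bool:
    if sorted(m.id for m in g1.motifs) != sorted(m.id for m in g2.motifs):
        return False
    for mid in (m.id for m in g1.motifs):
        r1, r2 = g1.branch[mid], g2.branch[mid]
        keys = set(r1) | set(r2)
        if any(abs(r1.get(k, 0) - r2.get(k, 0)) > tol for k in keys):
            return False
    return True


class TestSampleTutorGrammar:
    def test_determinism(self, tmp_path):
        g1 = s.sample_tutor_grammar(seed=7)
        g2 = s.sample_tutor_grammar(seed=7)
        assert g1.to_dict() == g2.to_dict()
        s.write_grammar(g1, tmp_path / "a.json")
        s.write_grammar(g2, tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == \
            (tmp_path / "b.json").read_bytes()

    def test_sampled_grammars_respect_constraints(self):
        """Motif counts/lengths in range; no branch transition at or above
        the 95% stereotypy threshold; 1-4 transitions per row."""
        for seed in range(200):
            g = s.sample_tutor_grammar(seed=seed)
            assert 3 <= len(g.motifs) <= 6
            for m in g.motifs:
                if m.is_repeat:
                    assert len(m.labels) == 1 and m.repeat_mean >= 1
                else:
                    assert 2 <= len(m.labels) <= 7
                row = g.row_excluding_end(m.id)
                assert 1 <= len(row) <= 4
                assert max(row.values()) < 0.95
                assert sum(g.branch[m.id].values()) == pytest.approx(1.0)

    def test_stereotyped_configuration_limit(self):
        cfg = s.GrammarConfig(stereotyped_fraction=1.0)
        g = s.sample_tutor_grammar(cfg, seed=3)
        for m in g.motifs:
            assert max(g.row_excluding_end(m.id).values()) >= 0.95

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            s.sample_tutor_grammar(s.GrammarConfig(motif_len_range=(1, 9)),
                                   seed=0)


class TestSampleCorpus:
    def test_deterministic_grammar_single_motif(self):
        g = s.Grammar(motifs=[s.GrammarMotif("m0", ("a", "b"))],
                      branch={"m0": {"<END>": 1.0}})
        c = s.sample_corpus(g, 10, seed=0, with_features=False)
        assert c.bout_labels == [("a", "b")] * 10

    def test_seeded_reproducibility(self, example_grammar):
        c1 = s.sample_corpus(example_grammar, 20, seed=9)
        c2 = s.sample_corpus(example_grammar, 20, seed=9)
        assert c1.bout_labels == c2.bout_labels

    def test_bout_length_near_target(self, example_grammar):
        c = s.sample_corpus(example_grammar, 300, seed=1,
                            with_features=False)
        mean_len = c.n_syllables / len(c.bouts)
        # geometric bout termination at p=0.05 per motif of mean length 2.75
        assert 45 < mean_len < 65

    def test_branch_probabilities_recovered(self, example_grammar):
        """Empirical branch transitions within 3 binomial SE of the
        generative row values at 500 bouts."""
        c = s.sample_corpus(example_grammar, 500, seed=2,
                            with_features=False)
        motifs = s.discover_motifs(c)
        bps, _ = s.classify_branch_points(c, motifs)
        for bp in bps:
            mid = next(m.id for m in example_grammar.motifs
                       if m.labels == bp.sequence.labels)
            truth = example_grammar.branch_transition_row(mid)
            assert bp.n_obs >= 50
            for lab, p in truth.items():
                se = math.sqrt(p * (1 - p) / bp.n_obs)
                assert abs(bp.transitions.get(lab, 0.0) - p) <= 3 * se + 1e-9

    def test_repeat_run_length_recovered(self):
        g = s.Grammar(
            motifs=[s.GrammarMotif("r", ("a",), repeat_mean=4.0),
                    s.GrammarMotif("m", ("b", "c"))],
            branch={"r": {"m": 0.95, "<END>": 0.05},
                    "m": {"r": 0.95, "<END>": 0.05}})
        c = s.sample_corpus(g, 500, seed=3, with_features=False)
        assert s.repeat_number(c, "a") == pytest.approx(4.0, abs=0.2)

    def test_gap_classes_ordered(self, example_grammar):
        g = s.Grammar.from_dict(example_grammar.to_dict())
        g.gap_model = {"within_motif": {"mu": math.log(10.0), "sigma": 0.4},
                       "between_motif": {"mu": math.log(60.0), "sigma": 0.5}}
        c = s.sample_corpus(g, 50, seed=4)
        motif_starts = {m.labels[0] for m in g.motifs}
        within, between = [], []
        for bout in c.bouts:
            for ev in bout.events[1:]:
                (between if ev.label in motif_starts else within).append(
                    ev.gap_before_ms)
        assert np.mean(between) > np.mean(within)

    def test_invalid_bout_count(self, example_grammar):
        with pytest.raises(ValueError):
            s.sample_corpus(example_grammar, 0, seed=0)


class TestDerivePupil:
    IDENTITY = dict(retention_intercept=50.0, retention_slope=0.0,
                    transition_noise_kappa=math.inf,
                    novel_syllable_rate=0.0, edit_rate=0.0,
                    feature_jitter=0.0)

    def test_identity_limit(self):
        """Retention 1, infinite kappa, no edits or novelty reproduces the
        tutor exactly (up to float renormalization)."""
        tutor = s.sample_tutor_grammar(seed=5)
        pupil, log = s.derive_pupil(tutor, s.LearningParams(**self.IDENTITY),
                                    seed=9)
        assert rows_close(tutor, pupil)
        assert {m.labels for m in pupil.motifs} == \
            {m.labels for m in tutor.motifs}
        assert log.edits == []
        assert log.motifs_dropped == []
        assert log.syllables_novel == set()
        assert pupil.feature_model == tutor.feature_model

    def test_degenerate_pupil_rejected(self):
        tutor = s.sample_tutor_grammar(seed=5)
        with pytest.raises(ValueError, match="degenerate"):
            s.derive_pupil(tutor,
                           s.LearningParams(retention_intercept=-50.0),
                           seed=1)

    def test_edit_log_replay(self):
        """Applying the edit log to the tutor reconstructs the pupil's
        structure exactly."""
        for seed in range(30):
            tutor = s.sample_tutor_grammar(seed=seed)
            try:
                pupil, log = s.derive_pupil(tutor, seed=seed + 1000)
            except ValueError:
                continue
            replayed = s.apply_edit_log(tutor, log)
            assert replayed.structural_signature() == \
                pupil.structural_signature()

    def test_retention_direction(self):
        """With a positive retention slope, branch transitions retained
        across a tutor's pupils are more prevalent in the tutor's song
        than dropped ones (pooling 3 pupils per tutor, as when several
        sons learn from one father)."""
        ok = valid = 0
        for seed in range(40):
            g = s.sample_tutor_grammar(
                s.GrammarConfig(with_features=False, with_gaps=False),
                seed=200 + seed)
            pi = g.stationary_distribution()
            q = {(i, j): pi[i] * pr for i in (m.id for m in g.motifs)
                 for j, pr in g.row_excluding_end(i).items()}
            tot = sum(q.values())
            prevs = {k: v / tot for k, v in q.items()}
            ret, dro = [], []
            for k in range(3):
                try:
                    _, log = s.derive_pupil(g, seed=1000 * seed + k)
                except ValueError:
                    continue
                ret += [prevs[t] for t in log.transitions_retained]
                dro += [prevs[t] for t in log.transitions_dropped]
            if ret and dro:
                valid += 1
                ok += float(np.mean(ret)) > float(np.mean(dro))
        assert valid >= 35
        assert ok / valid >= 0.9
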