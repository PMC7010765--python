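"""Shared fixtures: a hand-specified example grammar and small corpora."""

from __future__ import annotations

import pytest

import songseq as s


@pytest.fixture
def example_grammar() -> s.Grammar:
    """A fixed four-motif grammar mirroring a typical adult bird.

    One branch point has a strongly dominant (91%) transition next to
    rare alternatives, the others are more balanced, and every row
    terminates the bout 5% of the time (mean motif length 2.75 gives
    ~55-syllable bouts).  Specified explicitly so tests anchored to it
    are fully deterministic.
    """
    motifs = [
        s.GrammarMotif("m0", ("a", "b", "c", "d")),
        s.GrammarMotif("m1", ("e", "f")),
        s.GrammarMotif("m2", ("r", "t", "g")),
        s.GrammarMotif("m3", ("v", "w")),
    ]
    branch = {
        "m0": {"m1": 0.665, "m2": 0.285, "<END>": 0.05},
        "m1": {"m2": 0.5225, "m3": 0.4275, "<END>": 0.05},
        "m2": {"m0": 0.8645, "m3": 0.0665, "m1": 0.019, "<END>": 0.05},
        "m3": {"m0": 0.475, "m1": 0.475, "<END>": 0.05},
    }
    return s.Grammar(motifs=motifs, branch=branch, bout_length_mean=55.0)


@pytest.fixture
def example_corpus(example_grammar) -> s.SongCorpus:
    return s.sample_corpus(example_grammar, n_bouts=60, seed=100,
                           with_features=False)


def corpus_of(*bouts: str, bird_id: str = "bird") -> s.SongCorpus:
    """Shorthand: corpus_of('a b c', 'a b d')."""
    return s.SongCorpus.from_label_lists(bird_id,
                                         [b.split() for b in bouts])
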