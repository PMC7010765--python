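"""Discovery of motifs and branch points in a labelled corpus.

Bengalese finch song is organized into *motifs* — relatively stereotyped
chunks of 2-7 syllables — whose endings are followed either by a
stereotyped transition or by a *branch point*: a variable distribution
over following syllables with no single transition produced >= 95% of
the time.

Motif discovery here is greedy agglomeration on the first-order
transition graph.  Maximal runs of a single label are collapsed into a
repeat unit first; then adjacent units ``u -> v`` are merged into a chunk
whenever both the forward probability p(v follows u) and the backward
probability p(u precedes v) reach ``chain_threshold`` and the pair was
seen at least ``min_count`` times, iterating to a fixed point with
chunks treated as units.  Requiring both directions keeps a syllable
that is shared between two motifs from being chained across motif
boundaries.  Forward/backward probabilities use all occurrences of the
unit in their denominator, so bout boundaries dilute rather than hide
non-stereotyped transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .corpus import END, SongCorpus
from .sequence_stats import transition_entropy

# An atom is one motif position: a literal label, or a collapsed repeat run.
Atom = tuple[str, bool]  # (label, is_repeat)
Unit = tuple[Atom, ...]


@dataclass(frozen=True)
class Motif:
    """A stereotyped chunk of song.

    ``labels`` holds one label per motif position; a repeat motif is a
    single repeated label (``is_repeat`` true) whose typical run length is
    reported separately via :func:`songseq.sequence_stats.repeat_number`.
    """

    labels: tuple[str, ...]
    count: int = 0
    relative_prevalence: float = 0.0
    repeat_flags: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if not self.repeat_flags:
            object.__setattr__(self, "repeat_flags",
                               tuple(False for _ in self.labels))
        if len(self.repeat_flags) != len(self.labels):
            raise ValueError("repeat_flags must align with labels")

    @property
    def is_repeat(self) -> bool:
        return len(self.labels) == 1 and self.repeat_flags[0]

    @property
    def atoms(self) -> Unit:
        return tuple(zip(self.labels, self.repeat_flags))

    def __str__(self) -> str:
        return " ".join(l + ("+" if r else "")
                        for l, r in zip(self.labels, self.repeat_flags))


@dataclass
class BranchPoint:
    """A motif followed by a variable transition distribution.

    ``transitions`` excludes bout terminations (they are not syllable
    transitions); ``entropy_bits`` is the transition entropy of that
    distribution and ``dominant`` its highest-probability label (ties
    broken lexicographically).
    """

    sequence: Motif
    transitions: dict[str, float]
    n_obs: int
    entropy_bits: float = field(init=False)
    dominant: str = field(init=False)

    def __post_init__(self) -> None:
        if len(self.transitions) < 2:
            raise ValueError("a branch point requires >= 2 transitions")
        self.entropy_bits = transition_entropy(self.transitions)
        best = max(self.transitions.values())
        self.dominant = min(l for l, p in self.transitions.items()
                            if p == best)


def _collapse_runs(bouts: Sequence[Sequence[str]]) -> list[list[Unit]]:
    """Collapse maximal single-label runs; mark labels that ever repeat."""
    repeat_labels = set()
    for labels in bouts:
        for i in range(1, len(labels)):
            if labels[i] == labels[i - 1]:
                repeat_labels.add(labels[i])
    collapsed = []
    for labels in bouts:
        units: list[Unit] = []
        i = 0
        while i < len(labels):
            j = i
            while j < len(labels) and labels[j] == labels[i]:
                j += 1
            units.append((((labels[i], labels[i] in repeat_labels)),))
            i = j
    # note: a repeat label occurring once still collapses to its repeat unit,
    # so run-length variation does not split the unit inventory
        collapsed.append(units)
    return collapsed


def _pair_stats(bouts: list[list[Unit]]):
    pair_counts: dict[tuple[Unit, Unit], int] = {}
    unit_counts: dict[Unit, int] = {}
    for units in bouts:
        for u in units:
            unit_counts[u] = unit_counts.get(u, 0) + 1
        for a, b in zip(units, units[1:]):
            pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    return pair_counts, unit_counts


def _merge_pair(bouts: list[list[Unit]], pair: tuple[Unit, Unit]) -> None:
    u, v = pair
    merged = u + v
    for bi, units in enumerate(bouts):
        out: list[Unit] = []
        i = 0
        while i < len(units):
            if i + 1 < len(units) and units[i] == u and units[i + 1] == v:
                out.append(merged)
                i += 2
            else:
                out.append(units[i])
                i += 1
        bouts[bi] = out


def _flat(unit: Unit) -> tuple[str, ...]:
    return tuple(l for l, _ in unit)


def segment_units(corpus: SongCorpus,
                  chain_threshold: float = 0.75,
                  min_count: int = 5) -> list[list[Unit]]:
    """Run-collapse then chain to a fixed point; returns segmented bouts."""
    bouts = _collapse_runs(corpus.bout_labels)
    while True:
        pair_counts, unit_counts = _pair_stats(bouts)
        best: Optional[tuple[Unit, Unit]] = None
        best_key = None
        for (u, v), c in pair_counts.items():
            if u == v or c < min_count:
                continue
            if c / unit_counts[u] < chain_threshold:
                continue
            if c / unit_counts[v] < chain_threshold:
                continue
            key = (-c, _flat(u), _flat(v))  # deterministic choice
            if best_key is None or key < best_key:
                best, best_key = (u, v), key
        if best is None:
            return bouts
        _merge_pair(bouts, best)


def discover_motifs(corpus: SongCorpus,
                    chain_threshold: float = 0.75,
                    min_count: int = 5) -> list[Motif]:
    """Identify stereotyped chunks (motifs) by greedy bidirectional chaining.

    Returns chunks of length >= 2 plus single-syllable repeat motifs, with
    occurrence counts and relative prevalences (summing to 1 over the
    returned motifs).  A corpus with no qualifying pair and no repeats
    returns an empty list.
    """
    bouts = segment_units(corpus, chain_threshold, min_count)
    counts: dict[Unit, int] = {}
    for units in bouts:
        for u in units:
            if len(u) >= 2 or u[0][1]:  # chunk or repeat unit
                counts[u] = counts.get(u, 0) + 1
    # min_count also gates scoring, so rare incidental chunks are not motifs
    counts = {u: c for u, c in counts.items() if c >= min_count}
    total = sum(counts.values())
    motifs = [Motif(labels=_flat(u), count=c, relative_prevalence=c / total,
                    repeat_flags=tuple(r for _, r in u))
              for u, c in counts.items()]
    motifs.sort(key=lambda m: (-m.count, m.labels))
    return motifs


def _match_motif_at(labels: Sequence[str], i: int, motif: Motif) -> int:
    """Syllables consumed by ``motif`` matching at position ``i``, or 0."""
    pos = i
    for lab, is_rep in motif.atoms:
        if pos >= len(labels) or labels[pos] != lab:
            return 0
        pos += 1
        if is_rep:
            while pos < len(labels) and labels[pos] == lab:
                pos += 1
    return pos - i


def segment_with_motifs(corpus: SongCorpus, motifs: Sequence[Motif]
                        ) -> list[list[Optional[int]]]:
    """Greedy longest-match segmentation of each bout against a motif set.

    Returns, per bout, the segment list: an index into ``motifs`` for motif
    segments, ``None`` for single unmatched syllables.  Parallel consumed
    lengths are not returned; use the motif atoms to re-derive them.
    """
    order = sorted(range(len(motifs)),
                   key=lambda k: (-len(motifs[k].labels), -motifs[k].count,
                                  motifs[k].labels))
    segmented = []
    for labels in corpus.bout_labels:
        segs: list[Optional[int]] = []
        i = 0
        while i < len(labels):
            chosen, consumed = None, 1
            for k in order:
                c = _match_motif_at(labels, i, motifs[k])
                if c > 0 and (chosen is None or c > consumed):
                    chosen, consumed = k, c
            segs.append(chosen)
            i += consumed if chosen is not None else 1
        segmented.append(segs)
    return segmented


def following_transitions(corpus: SongCorpus, motifs: Sequence[Motif]
                          ) -> dict[int, dict[str, int]]:
    """Counts of the syllable immediately following each motif occurrence.

    The continuation of a motif segment is the first syllable of the next
    segment, or ``<END>`` when the motif is bout-final.
    """
    follow: dict[int, dict[str, int]] = {k: {} for k in range(len(motifs))}
    for labels, segs in zip(corpus.bout_labels,
                            segment_with_motifs(corpus, motifs)):
        # reconstruct segment start positions
        pos = 0
        starts = []
        for s in segs:
            starts.append(pos)
            if s is None:
                pos += 1
            else:
                pos += _match_motif_at(labels, pos, motifs[s])
        for si, s in enumerate(segs):
            if s is None:
                continue
            nxt = labels[starts[si + 1]] if si + 1 < len(segs) else END
            follow[s][nxt] = follow[s].get(nxt, 0) + 1
    return follow


def classify_branch_points(corpus: SongCorpus, motifs: Sequence[Motif],
                           stereotypy_threshold: float = 0.95
                           ) -> tuple[list[BranchPoint],
                                      list[tuple[Motif, str]]]:
    """Partition motifs into branch points and stereotyped continuations.

    For each motif the immediately following syllable is tallied over all
    occurrences, excluding bout terminations.  A motif whose dominant
    continuation reaches ``stereotypy_threshold`` (inclusive) is returned
    as a (motif, stereotyped-next) pair; all others become branch points.
    A motif that is always bout-final is classified stereotyped-to-END
    with a warning.
    """
    follow = following_transitions(corpus, motifs)
    branch_points: list[BranchPoint] = []
    stereotyped: list[tuple[Motif, str]] = []
    for k, motif in enumerate(motifs):
        row = {nxt: c for nxt, c in follow[k].items() if nxt != END}
        n_obs = sum(row.values())
        if n_obs == 0:
            warnings.warn(f"motif {motif} is always bout-final; "
                          "classified stereotyped-to-<END>")
            stereotyped.append((motif, END))
            continue
        probs = {nxt: c / n_obs for nxt, c in row.items()}
        best = max(probs.values())
        if best >= stereotypy_threshold or len(probs) < 2:
            dominant = min(l for l, p in probs.items() if p == best)
            stereotyped.append((motif, dominant))
        else:
            branch_points.append(BranchPoint(motif, probs, n_obs))
    return branch_points, stereotyped
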