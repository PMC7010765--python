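"""Element-level sequence statistics of a song corpus.

Implements the first-order Markov description of Bengalese finch song:
syllable prevalence, pairwise (and general fixed-context) transition
tables, transition entropy in bits, mean repeat numbers for repeated
syllables, and a split-half reliability check for transition-probability
estimates.

End-of-bout accounting
----------------------
Song bouts terminate, and a termination is not a syllable transition.
Probabilities are computed either over all continuations including the
``<END>`` pseudo-label (``include_end=True``, useful for diagnostics) or
renormalized over syllable transitions only (``include_end=False``, the
default used for branch-point probabilities and entropy, where bout
terminations immediately after the context are excluded).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .corpus import END, SongCorpus

logger = logging.getLogger(__name__)

Context = tuple[str, ...]

PROB_TOL = 1e-9


@dataclass
class PrevalenceTable:
    """Pooled counts of each label and its fraction of all syllables."""

    counts: dict[str, int]
    fractions: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total <= 0:
            raise ValueError("prevalence table requires at least one count")
        self.fractions = {l: c / total for l, c in self.counts.items()}


@dataclass
class TransitionTable:
    """Per-context counts and probabilities of next-element transitions.

    ``counts`` always includes ``<END>`` continuations; ``probabilities``
    are computed with ``<END>`` included or excluded per ``include_end``.
    Contexts whose only continuation is ``<END>`` have an empty probability
    row when ``include_end`` is false.
    """

    context_order: int
    counts: dict[Context, dict[str, int]]
    include_end: bool
    min_count: int = 1
    probabilities: dict[Context, dict[str, float]] = field(init=False)

    def __post_init__(self) -> None:
        if self.context_order < 1:
            raise ValueError("context_order must be >= 1")
        self.probabilities = {}
        for ctx, row in self.counts.items():
            kept = {nxt: c for nxt, c in row.items()
                    if c >= self.min_count and (self.include_end or nxt != END)}
            total = sum(kept.values())
            self.probabilities[ctx] = (
                {nxt: c / total for nxt, c in kept.items()} if total else {})

    def row(self, context: Union[str, Context]) -> dict[str, float]:
        if isinstance(context, str):
            context = (context,)
        return self.probabilities[context]


def syllable_prevalence(corpus: SongCorpus) -> PrevalenceTable:
    """Relative prevalence of each syllable type, pooled over all bouts."""
    counts: dict[str, int] = {}
    for bout in corpus.bouts:
        for ev in bout.events:
            counts[ev.label] = counts.get(ev.label, 0) + 1
    return PrevalenceTable(counts)


def _count_transitions(bouts: Iterable[Sequence[str]], order: int
                       ) -> dict[Context, dict[str, int]]:
    counts: dict[Context, dict[str, int]] = {}
    for labels in bouts:
        n = len(labels)
        for i in range(order - 1, n):
            ctx = tuple(labels[i - order + 1:i + 1])
            nxt = labels[i + 1] if i + 1 < n else END
            row = counts.setdefault(ctx, {})
            row[nxt] = row.get(nxt, 0) + 1
    return counts


def pairwise_transitions(corpus: SongCorpus, include_end: bool = False,
                         min_count: int = 1) -> TransitionTable:
    """First-order transition table over adjacent within-bout pairs.

    Each adjacent pair is counted once; the final syllable of every bout
    contributes an ``<END>`` count.
    """
    counts = _count_transitions(corpus.bout_labels, order=1)
    return TransitionTable(1, counts, include_end=include_end,
                           min_count=min_count)


def context_transitions(corpus: SongCorpus, contexts: Sequence[Context],
                        include_end: bool = False) -> TransitionTable:
    """Transition table restricted to the given fixed label-tuple contexts.

    Contexts may have different lengths (e.g. the motif inventory of a
    bird).  Occurrences are contiguous matches of the context within a
    bout; the continuation is the label immediately following the match
    (or ``<END>`` at a bout boundary).
    """
    if not contexts:
        raise ValueError("at least one context required")
    counts: dict[Context, dict[str, int]] = {}
    for labels in corpus.bout_labels:
        n = len(labels)
        for ctx in set(contexts):
            L = len(ctx)
            for i in range(n - L + 1):
                if tuple(labels[i:i + L]) != ctx:
                    continue
                nxt = labels[i + L] if i + L < n else END
                row = counts.setdefault(ctx, {})
                row[nxt] = row.get(nxt, 0) + 1
    return TransitionTable(max(len(c) for c in contexts), counts,
                           include_end=include_end)


def transition_entropy(probabilities: Union[Mapping[str, float],
                                            Sequence[float]]) -> float:
    """Transition entropy sum(-p_i * log2(p_i)) in bits.

    ``probabilities`` must be nonnegative and sum to 1 (tolerance 1e-9);
    zero-probability entries contribute 0.
    """
    p = np.asarray(list(probabilities.values())
                   if isinstance(probabilities, Mapping) else probabilities,
                   dtype=float)
    if p.size == 0:
        raise ValueError("empty probability distribution")
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > PROB_TOL:
        raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def repeat_number(corpus: SongCorpus, label: str) -> float:
    """Mean length of maximal consecutive runs of ``label`` across bouts."""
    runs = []
    for labels in corpus.bout_labels:
        i, n = 0, len(labels)
        while i < n:
            if labels[i] == label:
                j = i
                while j < n and labels[j] == label:
                    j += 1
                runs.append(j - i)
                i = j
            else:
                i += 1
    if not runs:
        raise ValueError(f"label {label!r} does not occur in corpus")
    return float(np.mean(runs))


def split_half_reliability(corpus: SongCorpus, contexts: Sequence[Context],
                           seed: int, include_end: bool = False,
                           halves: tuple[Sequence[int], Sequence[int]] | None = None,
                           ) -> dict:
    """Split the corpus in half by bout and correlate transition probabilities.

    Bouts are randomly partitioned into two halves of near-equal size
    (``seed`` controls the shuffle; pass explicit bout-index ``halves`` to
    override).  Transition probabilities at each requested context are
    estimated per half and paired over the union of transitions observed in
    either half (a transition absent from one half contributes probability
    0 there).  Returns ``r_squared`` (squared Pearson correlation of the
    paired probabilities) and the per-half tables.

    Contexts absent from both halves are excluded with a warning; if no
    transitions remain, ``r_squared`` is ``nan``.
    """
    if len(corpus.bouts) < 2:
        raise ValueError("split-half reliability requires at least 2 bouts")
    if halves is None:
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(corpus.bouts))
        halves = (idx[: len(idx) // 2], idx[len(idx) // 2:])
    sub = []
    for h in halves:
        bouts = [corpus.bouts[i] for i in h]
        sub.append(SongCorpus(f"{corpus.bird_id}-half", bouts))
    t1 = context_transitions(sub[0], contexts, include_end=include_end)
    t2 = context_transitions(sub[1], contexts, include_end=include_end)

    xs, ys = [], []
    for ctx in contexts:
        r1 = t1.probabilities.get(ctx, {})
        r2 = t2.probabilities.get(ctx, {})
        if not r1 and not r2:
            warnings.warn(f"context {ctx} absent from both halves; excluded")
            continue
        for nxt in sorted(set(r1) | set(r2)):
            xs.append(r1.get(nxt, 0.0))
            ys.append(r2.get(nxt, 0.0))
    if len(xs) < 2 or np.std(xs) == 0 or np.std(ys) == 0:
        r2_val = float("nan")
    else:
        r2_val = float(np.corrcoef(xs, ys)[0, 1] ** 2)
    return {"r_squared": r2_val, "half_tables": (t1, t2),
            "pairs": list(zip(xs, ys))}
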