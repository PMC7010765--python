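"""Tutor-pupil comparison at four levels of song organization.

Given a tutor corpus and a pupil corpus sharing a label space (or linked
by an explicit label map), this module classifies song elements as
retained / dropped / novel at the levels of syllable repertoire, pairwise
transitions, motifs, and branch points; aligns motifs and scores syllable
additions and deletions by motif position (beginning / middle / end);
builds positional chance models from the tutor's motif-length multiset;
tests observed edit-position distributions against chance with a
likelihood-ratio (G) test; and quantifies branch-point copying fidelity
as the total deviation in transition probability (a 0-200% scaled L1
distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .corpus import SongCorpus
from .sequence_stats import PROB_TOL, transition_entropy
from .structure import BranchPoint, Motif

EditType = Literal["addition", "deletion"]
Position = Literal["beginning", "middle", "end"]
POSITIONS: tuple[Position, ...] = ("beginning", "middle", "end")


class PairExcludedError(ValueError):
    """A tutor-pupil pair cannot enter an analysis (e.g. one class empty)."""


@dataclass
class RepertoireMap:
    """Partition of the two repertoires into retained / dropped / novel."""

    retained: set[str]
    dropped: set[str]
    novel: set[str]
    pct_retained_of_tutor: float = field(init=False)
    pct_novel_of_pupil: float = field(init=False)

    def __post_init__(self) -> None:
        n_tutor = len(self.retained) + len(self.dropped)
        n_pupil = len(self.retained) + len(self.novel)
        self.pct_retained_of_tutor = (
            100.0 * len(self.retained) / n_tutor if n_tutor else float("nan"))
        self.pct_novel_of_pupil = (
            100.0 * len(self.novel) / n_pupil if n_pupil else float("nan"))


@dataclass(frozen=True)
class EditRecord:
    """One syllable addition or deletion within a modified motif."""

    type: EditType
    position: Position
    label: str
    tutor_motif: tuple[str, ...]
    pupil_motif: tuple[str, ...]


@dataclass
class MotifComparison:
    status: Literal["matched", "modified", "dropped"]
    tutor_motif: Motif
    best_pupil_motif: Optional[Motif]
    shared_fraction: float
    edits: list[EditRecord]


@dataclass
class BranchPointComparison:
    status: Literal["retained", "dropped_sequence",
                    "dropped_stereotyped_in_pupil"]
    tutor_bp: BranchPoint
    retained_transitions: set[str] = field(default_factory=set)
    dropped_transitions: set[str] = field(default_factory=set)
    novel_transitions: set[str] = field(default_factory=set)
    total_deviation_pct: Optional[float] = None
    dominant_match: Optional[bool] = None
    entropy_tutor: Optional[float] = None
    entropy_pupil: Optional[float] = None
    pupil_stereotyped_next: Optional[str] = None


def map_repertoire(tutor: SongCorpus, pupil: SongCorpus,
                   label_map: Optional[Mapping[str, str]] = None
                   ) -> RepertoireMap:
    """Classify syllable types as retained, dropped (tutor-only) or novel.

    ``label_map`` translates pupil labels into the tutor's label space when
    the corpora were labelled independently; it must be injective on the
    tutor targets.
    """
    tutor_set = tutor.repertoire
    pupil_set = pupil.repertoire
    if label_map is not None:
        targets = [label_map[l] for l in pupil_set if l in label_map]
        if len(targets) != len(set(targets)):
            raise ValueError("label_map maps multiple pupil labels to one "
                             "tutor label")
        pupil_set = {label_map.get(l, l) for l in pupil_set}
    retained = tutor_set & pupil_set
    return RepertoireMap(retained=retained, dropped=tutor_set - pupil_set,
                         novel=pupil_set - tutor_set)


def prevalence_by_retention(tutor_elements: Mapping, retained: Iterable,
                            dropped: Iterable) -> dict:
    """Mean tutor prevalence of retained vs dropped elements.

    Pairs in which one class is empty are excluded from this analysis;
    such input raises :class:`PairExcludedError`.  Returns group means and
    a tidy per-element table for downstream model fitting.
    """
    retained, dropped = set(retained), set(dropped)
    if not retained or not dropped:
        raise PairExcludedError("pair excluded: all elements retained or "
                                "all elements dropped")
    table = [{"element": e, "prevalence": p,
              "status": "retained" if e in retained else
                        "dropped" if e in dropped else "other"}
             for e, p in tutor_elements.items()]
    mean_ret = float(np.mean([r["prevalence"] for r in table
                              if r["status"] == "retained"]))
    mean_drop = float(np.mean([r["prevalence"] for r in table
                               if r["status"] == "dropped"]))
    return {"mean_retained": mean_ret, "mean_dropped": mean_drop,
            "table": table}


def _lcs_backbone(tutor: Sequence[str], pupil: Sequence[str]
                  ) -> list[tuple[int, int]]:
    """Longest common subsequence as (tutor_idx, pupil_idx) match pairs.

    Ties are broken leftmost-greedily in the tutor sequence: when skipping
    either side preserves the LCS length, the pupil side is advanced first,
    so matches bind to the earliest tutor syllables.
    """
    n, m = len(tutor), len(pupil)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if tutor[i] == pupil[j]:
                dp[i, j] = dp[i + 1, j + 1] + 1
            else:
                dp[i, j] = max(dp[i + 1, j], dp[i, j + 1])
    pairs = []
    i = j = 0
    while i < n and j < m:
        if tutor[i] == pupil[j] and dp[i, j] == dp[i + 1, j + 1] + 1:
            pairs.append((i, j))
            i += 1
            j += 1
        elif dp[i, j + 1] >= dp[i + 1, j]:
            j += 1
        else:
            i += 1
    return pairs


def shared_fraction(tutor_motif: Sequence[str],
                    pupil_motif: Sequence[str]) -> float:
    """Order-preserving matched tutor syllables / tutor motif length."""
    return len(_lcs_backbone(tutor_motif, pupil_motif)) / len(tutor_motif)


def _slot_position(idx: int, length: int) -> Position:
    if idx == 0:
        return "beginning"
    if idx == length - 1:
        return "end"
    return "middle"


def score_motif_edits(tutor_motif: Sequence[str],
                      pupil_motif: Sequence[str]) -> list[EditRecord]:
    """Score syllable additions and deletions between two motif versions.

    The order-preserving backbone is the longest common subsequence.
    Unmatched tutor syllables are deletions positioned by their slot in
    the tutor motif (first syllable = beginning, last = end, otherwise
    middle).  Unmatched pupil syllables are additions positioned relative
    to the backbone: before the first backbone match = beginning, after
    the last = end, otherwise middle.  A pair of motifs with no common
    syllable is not comparable and raises ``ValueError``.
    """
    tutor_motif = tuple(tutor_motif)
    pupil_motif = tuple(pupil_motif)
    if tutor_motif == pupil_motif:
        return []
    backbone = _lcs_backbone(tutor_motif, pupil_motif)
    if not backbone:
        raise ValueError("not comparable: motifs share no ordered syllables")
    matched_t = {i for i, _ in backbone}
    matched_p = {j for _, j in backbone}
    first_p = min(matched_p)
    last_p = max(matched_p)
    edits: list[EditRecord] = []
    for i, lab in enumerate(tutor_motif):
        if i not in matched_t:
            edits.append(EditRecord("deletion",
                                    _slot_position(i, len(tutor_motif)),
                                    lab, tutor_motif, pupil_motif))
    for j, lab in enumerate(pupil_motif):
        if j in matched_p:
            continue
        pos: Position = ("beginning" if j < first_p
                         else "end" if j > last_p else "middle")
        edits.append(EditRecord("addition", pos, lab,
                                tutor_motif, pupil_motif))
    return edits


def count_edit_positions(edits: Iterable[EditRecord], edit_type: EditType,
                         per_instance: bool = False
                         ) -> tuple[int, int, int]:
    """Tally edits of one type into (beginning, middle, end) counts.

    ``per_instance`` collapses multiple edits of the same type at the same
    position within the same motif pair into a single instance (the
    block-counting convention for runs of added syllables).
    """
    seen = set()
    counts = {p: 0 for p in POSITIONS}
    for e in edits:
        if e.type != edit_type:
            continue
        if per_instance:
            key = (e.tutor_motif, e.pupil_motif, e.position)
            if key in seen:
                continue
            seen.add(key)
        counts[e.position] += 1
    return counts["beginning"], counts["middle"], counts["end"]


def classify_motif(tutor_motif: Motif, pupil_motifs: Sequence[Motif],
                   threshold: float = 0.5) -> MotifComparison:
    """Match one tutor motif against the pupil's motif inventory.

    The best pupil motif maximizes the shared fraction (ties broken by
    pupil-motif prevalence, then lexicographically).  The motif is
    ``matched`` if identical, ``modified`` if the shared fraction reaches
    ``threshold`` (inclusive), otherwise ``dropped``.
    """
    best: Optional[Motif] = None
    best_key = None
    for pm in pupil_motifs:
        frac = shared_fraction(tutor_motif.labels, pm.labels)
        key = (-frac, -pm.relative_prevalence, pm.labels)
        if best_key is None or key < best_key:
            best, best_key = pm, key
    if best is None:
        return MotifComparison("dropped", tutor_motif, None, 0.0, [])
    frac = -best_key[0]
    if tutor_motif.labels == best.labels:
        return MotifComparison("matched", tutor_motif, best, frac, [])
    if frac >= threshold:
        edits = score_motif_edits(tutor_motif.labels, best.labels)
        return MotifComparison("modified", tutor_motif, best, frac, edits)
    return MotifComparison("dropped", tutor_motif, None, frac, [])


def match_motifs(tutor_motifs: Sequence[Motif],
                 pupil_motifs: Sequence[Motif],
                 threshold: float = 0.5) -> list[MotifComparison]:
    """Greedy one-to-one assignment of tutor motifs to pupil motifs.

    Pairs are taken in decreasing order of shared fraction (ties by pupil
    prevalence then labels); each motif participates in at most one pair.
    """
    candidates = []
    for ti, tm in enumerate(tutor_motifs):
        for pi, pm in enumerate(pupil_motifs):
            frac = shared_fraction(tm.labels, pm.labels)
            if frac > 0:
                candidates.append((-frac, -pm.relative_prevalence,
                                   tm.labels, pm.labels, ti, pi))
    candidates.sort()
    used_t: set[int] = set()
    used_p: set[int] = set()
    assigned: dict[int, tuple[int, float]] = {}
    for negfrac, _, _, _, ti, pi in candidates:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        assigned[ti] = (pi, -negfrac)
    out = []
    for ti, tm in enumerate(tutor_motifs):
        if ti not in assigned:
            out.append(MotifComparison("dropped", tm, None, 0.0, []))
            continue
        pi, frac = assigned[ti]
        pm = pupil_motifs[pi]
        if tm.labels == pm.labels:
            out.append(MotifComparison("matched", tm, pm, frac, []))
        elif frac >= threshold:
            out.append(MotifComparison("modified", tm, pm, frac,
                                       score_motif_edits(tm.labels, pm.labels)))
        else:
            out.append(MotifComparison("dropped", tm, None, frac, []))
    return out


def position_chance_model(motif_lengths: Sequence[int],
                          edit_type: EditType
                          ) -> tuple[float, float, float]:
    """Chance probabilities of an edit at the beginning / middle / end.

    Pooled-slot model over the tutor's motif-length multiset: a motif of
    length L offers deletion slots (1 beginning, L-2 middle, 1 end) — its
    syllables — and insertion slots (1, L-1, 1) — the L+1 positions a
    syllable can be inserted at.  Class probabilities are pooled class
    sums over all motifs divided by the total slot count.
    """
    if any(L < 2 for L in motif_lengths):
        raise ValueError("motif lengths must be >= 2")
    if not motif_lengths:
        raise ValueError("at least one motif length required")
    beg = mid = end = 0
    for L in motif_lengths:
        if edit_type == "deletion":
            beg, mid, end = beg + 1, mid + (L - 2), end + 1
        else:
            beg, mid, end = beg + 1, mid + (L - 1), end + 1
    total = beg + mid + end
    return beg / total, mid / total, end / total


def expected_edit_counts(n_edits: int,
                         probs: Sequence[float]) -> tuple[float, ...]:
    """Expected (beginning, middle, end) counts under the chance model."""
    if abs(sum(probs) - 1.0) > PROB_TOL:
        raise ValueError("chance probabilities must sum to 1")
    return tuple(n_edits * p for p in probs)


def g_test(observed: Sequence[int],
           expected_probs: Sequence[float]) -> dict:
    """Likelihood-ratio goodness-of-fit test of counts against probabilities.

    G = 2 * sum O_i * ln(O_i / E_i) with E_i = N * p_i and 0*ln(0) = 0;
    the p-value is the chi-square upper tail with k-1 degrees of freedom.
    """
    obs = np.asarray(observed, dtype=float)
    probs = np.asarray(expected_probs, dtype=float)
    n = obs.sum()
    if n <= 0:
        raise ValueError("observed counts must sum to > 0")
    if abs(probs.sum() - 1.0) > PROB_TOL:
        raise ValueError("expected probabilities must sum to 1")
    if np.any((probs <= 0) & (obs > 0)):
        raise ValueError("zero expected probability with nonzero observed "
                         "count")
    expected = n * probs
    nz = obs > 0
    g = 2.0 * float((obs[nz] * np.log(obs[nz] / expected[nz])).sum())
    df = len(obs) - 1
    return {"G": g, "df": df, "p": float(stats.chi2.sf(g, df))}


def total_deviation(tutor_dist: Mapping[str, float],
                    pupil_dist: Mapping[str, float]) -> float:
    """Total deviation in transition probability, in percent (0-200).

    100 times the sum, over the union of transition labels, of the
    absolute difference in probability (a label absent from one bird has
    probability 0 there).  0% when the pupil perfectly matches the tutor;
    200% when no transition is shared.
    """
    for name, d in (("tutor", tutor_dist), ("pupil", pupil_dist)):
        if abs(sum(d.values()) - 1.0) > PROB_TOL:
            raise ValueError(f"{name} distribution does not sum to 1")
    labels = set(tutor_dist) | set(pupil_dist)
    return 100.0 * sum(abs(tutor_dist.get(l, 0.0) - pupil_dist.get(l, 0.0))
                       for l in labels)


def compare_branch_point(tutor_bp: BranchPoint,
                         motif_comparisons: Sequence[MotifComparison],
                         pupil_branch_points: Sequence[BranchPoint],
                         pupil_stereotyped: Sequence[tuple[Motif, str]] = (),
                         ) -> BranchPointComparison:
    """Compare one tutor branch point against the pupil's song structure.

    The branch point is ``dropped_sequence`` if its sequence motif was
    dropped by the pupil, ``dropped_stereotyped_in_pupil`` if the pupil
    follows the retained sequence with a stereotyped (>= 95%) transition
    (recording whether that transition is the tutor's dominant one), and
    otherwise ``retained``, with the transition sets partitioned and the
    total deviation in transition probability computed over the union.
    """
    seq = tutor_bp.sequence.labels
    comp = next((c for c in motif_comparisons
                 if c.tutor_motif.labels == seq), None)
    pupil_seq = None
    if comp is not None and comp.status in ("matched", "modified"):
        pupil_seq = comp.best_pupil_motif.labels
    if pupil_seq is None:
        return BranchPointComparison("dropped_sequence", tutor_bp,
                                     dropped_transitions=set(tutor_bp.transitions),
                                     entropy_tutor=tutor_bp.entropy_bits)
    for motif, nxt in pupil_stereotyped:
        if motif.labels == pupil_seq:
            return BranchPointComparison(
                "dropped_stereotyped_in_pupil", tutor_bp,
                dominant_match=(nxt == tutor_bp.dominant),
                entropy_tutor=tutor_bp.entropy_bits,
                pupil_stereotyped_next=nxt)
    pupil_bp = next((bp for bp in pupil_branch_points
                     if bp.sequence.labels == pupil_seq), None)
    if pupil_bp is None:
        # retained motif but never followed by song in the pupil
        return BranchPointComparison("dropped_sequence", tutor_bp,
                                     dropped_transitions=set(tutor_bp.transitions),
                                     entropy_tutor=tutor_bp.entropy_bits)
    t_set = set(tutor_bp.transitions)
    p_set = set(pupil_bp.transitions)
    return BranchPointComparison(
        "retained", tutor_bp,
        retained_transitions=t_set & p_set,
        dropped_transitions=t_set - p_set,
        novel_transitions=p_set - t_set,
        total_deviation_pct=total_deviation(tutor_bp.transitions,
                                            pupil_bp.transitions),
        dominant_match=(tutor_bp.dominant == pupil_bp.dominant),
        entropy_tutor=tutor_bp.entropy_bits,
        entropy_pupil=pupil_bp.entropy_bits)
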