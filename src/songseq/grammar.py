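"""Generative song grammars: tutor sampling, pupil derivation, bout sampling.

A :class:`Grammar` is a motif-level first-order Markov model of Bengalese
finch song: a set of motifs (stereotyped label chunks, including repeat
motifs with geometric run lengths), a branch matrix giving the
probability of each next motif (or bout termination) after each motif, a
per-label Gaussian acoustic-feature model, and lognormal gap-duration
models for within- versus between-motif silent intervals.  The observed
branch-point transition after a motif is the first syllable of the next
motif.

The synthetic pipeline stands in for recorded song: ``sample_tutor_grammar``
draws a tutor with realistic structure (3-6 motifs of 2-7 syllables,
~55-syllable bouts, no branch transition at or above the 95% stereotypy
threshold unless configured), ``derive_pupil`` applies a parameterized
learning model (prevalence-dependent retention, noisy transition-
probability copying, position-biased single-syllable motif edits, novel
elements) and returns the pupil grammar together with a ground-truth
:class:`EditLog`, and ``sample_corpus`` draws seeded bout corpora.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .corpus import END, Bout, SongCorpus, SyllableEvent
from .compare import EditRecord, _slot_position

ROW_TOL = 1e-9

FEATURE_NAMES = ("mean_frequency_hz", "duration_ms",
                 "spectrotemporal_entropy", "amplitude_entropy",
                 "spectral_entropy")


@dataclass(frozen=True)
class GrammarMotif:
    """One motif of a grammar; ``repeat_mean`` set for repeat motifs."""

    id: str
    labels: tuple[str, ...]
    repeat_mean: Optional[float] = None

    def __post_init__(self) -> None:
        if self.repeat_mean is not None:
            if len(self.labels) != 1:
                raise ValueError("a repeat motif has exactly one label")
            if self.repeat_mean < 1.0:
                raise ValueError("repeat_mean must be >= 1")
        elif not 2 <= len(self.labels) <= 7:
            raise ValueError(f"motif {self.id}: length must be in [2, 7]")

    @property
    def is_repeat(self) -> bool:
        return self.repeat_mean is not None

    @property
    def expected_length(self) -> float:
        return self.repeat_mean if self.is_repeat else float(len(self.labels))


@dataclass
class Grammar:
    """Generative song model; see module docstring."""

    motifs: list[GrammarMotif]
    branch: dict[str, dict[str, float]]  # motif id -> {motif id | <END>: p}
    bout_length_mean: float = 55.5
    max_syllables: int = 200
    feature_model: Optional[dict[str, dict[str, tuple[float, float]]]] = None
    gap_model: Optional[dict[str, dict[str, float]]] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [m.id for m in self.motifs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate motif ids")
        known = set(ids)
        if set(self.branch) != known:
            raise ValueError("branch matrix rows must cover exactly the "
                             "motif ids")
        for mid, row in self.branch.items():
            for target in row:
                if target != END and target not in known:
                    raise ValueError(f"branch row {mid!r} references unknown "
                                     f"motif {target!r}")
                if row[target] < 0:
                    raise ValueError(f"negative probability in row {mid!r}")
            s = sum(row.values())
            # boundary inclusive: a deviation of exactly 1e-9 is accepted
            if abs(s - 1.0) - ROW_TOL > 1e-12:
                raise ValueError(f"branch row {mid!r} sums to {s!r}, not 1")
        if self.gap_model is not None:
            w = self.gap_model["within_motif"]
            b = self.gap_model["between_motif"]
            if _lognormal_mean(**b) <= _lognormal_mean(**w):
                raise ValueError("between-motif gaps must be longer on "
                                 "average than within-motif gaps")

    # -- lookups ---------------------------------------------------------
    def motif_by_id(self, mid: str) -> GrammarMotif:
        return next(m for m in self.motifs if m.id == mid)

    @property
    def labels(self) -> set[str]:
        return {l for m in self.motifs for l in m.labels}

    def row_excluding_end(self, mid: str) -> dict[str, float]:
        row = {t: p for t, p in self.branch[mid].items() if t != END and p > 0}
        total = sum(row.values())
        return {t: p / total for t, p in row.items()} if total else {}

    def branch_transition_row(self, mid: str) -> dict[str, float]:
        """Observable branch transitions: first syllable of each next motif."""
        out: dict[str, float] = {}
        for t, p in self.row_excluding_end(mid).items():
            first = self.motif_by_id(t).labels[0]
            out[first] = out.get(first, 0.0) + p
        return out

    def stationary_distribution(self) -> dict[str, float]:
        """Stationary motif frequencies of the END-conditioned chain."""
        ids = [m.id for m in self.motifs]
        k = len(ids)
        P = np.zeros((k, k))
        for i, mid in enumerate(ids):
            row = self.row_excluding_end(mid)
            if not row:  # motif that always ends the bout: renewal restart
                P[i, :] = 1.0 / k
            for j, tid in enumerate(ids):
                P[i, j] = row.get(tid, P[i, j])
        x = np.full(k, 1.0 / k)
        for _ in range(500):
            x = x @ P
            s = x.sum()
            if s == 0:
                raise ValueError("absorbing grammar with unreachable motifs")
            x = x / s
        return dict(zip(ids, x.tolist()))

    def expected_syllable_prevalence(self) -> dict[str, float]:
        """Long-run relative frequency of each syllable label."""
        pi = self.stationary_distribution()
        weights: dict[str, float] = {}
        for m in self.motifs:
            per_occ = ({m.labels[0]: m.repeat_mean} if m.is_repeat
                       else {l: m.labels.count(l) * 1.0 for l in m.labels})
            for lab, w in per_occ.items():
                weights[lab] = weights.get(lab, 0.0) + pi[m.id] * w
        total = sum(weights.values())
        return {lab: w / total for lab, w in weights.items()}

    def structural_signature(self):
        """Motifs and branch matrix only (no feature/gap models)."""
        motifs = tuple(sorted((m.id, m.labels, m.repeat_mean)
                              for m in self.motifs))
        rows = tuple(sorted((mid, tuple(sorted(row.items())))
                            for mid, row in self.branch.items()))
        return motifs, rows

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "motifs": [{"id": m.id, "labels": list(m.labels),
                        "repeat_mean": m.repeat_mean} for m in self.motifs],
            "branch": {mid: dict(row) for mid, row in self.branch.items()},
            "bout_length_mean": self.bout_length_mean,
            "max_syllables": self.max_syllables,
            "feature_model": (None if self.feature_model is None else
                              {lab: {f: list(mv) for f, mv in fm.items()}
                               for lab, fm in self.feature_model.items()}),
            "gap_model": self.gap_model,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Grammar":
        motifs = [GrammarMotif(m["id"], tuple(m["labels"]),
                               m.get("repeat_mean"))
                  for m in data["motifs"]]
        fm = data.get("feature_model")
        if fm is not None:
            fm = {lab: {f: tuple(mv) for f, mv in d.items()}
                  for lab, d in fm.items()}
        return cls(motifs=motifs,
                   branch={mid: dict(row)
                           for mid, row in data["branch"].items()},
                   bout_length_mean=data.get("bout_length_mean", 55.5),
                   max_syllables=data.get("max_syllables", 200),
                   feature_model=fm,
                   gap_model=data.get("gap_model"))


def _lognormal_mean(mu: float, sigma: float) -> float:
    return math.exp(mu + sigma ** 2 / 2.0)


def _label_name(i: int) -> str:
    if i < 26:
        return chr(97 + i)
    return chr(97 + i // 26 - 1) + chr(97 + i % 26)


@dataclass
class GrammarConfig:
    """Ranges and constraints for tutor-grammar sampling.

    Defaults follow the typical structure of adult Bengalese finch song:
    3-6 motifs per bird of 2-7 syllables (one of them a repeat motif with
    a characteristic run length of 2-5), bouts of about 55 syllables, and
    branch rows in which no transition reaches the 95% stereotypy
    threshold.  ``branch_uniform_mix`` blends each Dirichlet row draw with
    the uniform distribution so every transition keeps non-negligible
    probability (rare transitions exist but are observable at realistic
    corpus sizes); ``max_branch_prob`` bounds the largest termination-
    excluded transition probability in a non-stereotyped row.
    """

    n_motifs_range: tuple[int, int] = (3, 6)
    motif_len_range: tuple[int, int] = (2, 7)
    n_successors_range: tuple[int, int] = (2, 4)
    n_repeat_motifs: int = 1
    repeat_mean_range: tuple[float, float] = (2.0, 5.0)
    bout_length_mean: float = 55.5
    max_syllables: int = 200
    max_branch_prob: float = 0.95
    branch_uniform_mix: float = 0.2
    stereotyped_fraction: float = 0.0
    stereotyped_prob: float = 0.97
    with_features: bool = True
    with_gaps: bool = True

    def validate(self) -> None:
        lo, hi = self.n_motifs_range
        if not 1 <= lo <= hi:
            raise ValueError("infeasible n_motifs_range")
        llo, lhi = self.motif_len_range
        if not (2 <= llo <= lhi <= 7):
            raise ValueError("motif_len_range must lie within [2, 7]")
        if self.n_repeat_motifs < 0:
            raise ValueError("n_repeat_motifs must be >= 0")
        if not 0 < self.max_branch_prob <= 1:
            raise ValueError("max_branch_prob must be in (0, 1]")


def _draw_branch_row(rng: np.random.Generator, k: int, mix: float,
                     cap: float) -> np.ndarray:
    """A length-k probability vector with every entry < cap (strict)."""
    uniform = np.full(k, 1.0 / k)
    if k == 1:
        return np.ones(1)
    for _ in range(1000):
        w = (1.0 - mix) * rng.dirichlet(np.ones(k)) + mix * uniform
        if w.max() < cap:
            return w
    return uniform  # cap below 1/k is infeasible; fall back to uniform


def sample_tutor_grammar(config: Optional[GrammarConfig] = None,
                         seed: int = 0) -> Grammar:
    """Draw a random tutor grammar; deterministic given (config, seed)."""
    config = config or GrammarConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    n_motifs = int(rng.integers(config.n_motifs_range[0],
                                config.n_motifs_range[1] + 1))
    n_repeats = min(config.n_repeat_motifs, max(n_motifs - 2, 0))

    motifs: list[GrammarMotif] = []
    next_label = 0
    for i in range(n_motifs):
        mid = f"m{i}"
        if i >= n_motifs - n_repeats:
            lab = _label_name(next_label)
            next_label += 1
            mean = float(rng.uniform(*config.repeat_mean_range))
            motifs.append(GrammarMotif(mid, (lab,), repeat_mean=mean))
        else:
            length = int(rng.integers(config.motif_len_range[0],
                                      config.motif_len_range[1] + 1))
            labels = tuple(_label_name(next_label + j) for j in range(length))
            next_label += length
            motifs.append(GrammarMotif(mid, labels))

    mean_len = float(np.mean([m.expected_length for m in motifs]))
    end_prob = min(mean_len / config.bout_length_mean, 0.5)

    # a permutation cycle keeps every motif reachable; extra successors are
    # drawn on top so each branch point offers 2-4 distinct transitions
    ids = [m.id for m in motifs]
    cycle = [ids[i] for i in rng.permutation(n_motifs)]
    cycle_next = {cycle[i]: cycle[(i + 1) % n_motifs]
                  for i in range(n_motifs)}
    branch: dict[str, dict[str, float]] = {}
    for m in motifs:
        available = [x.id for x in motifs
                     if not (m.is_repeat and x.id == m.id)]
        lo = min(config.n_successors_range[0], len(available))
        hi = min(config.n_successors_range[1], len(available))
        n_succ = int(rng.integers(lo, hi + 1))
        successors = [cycle_next[m.id]] if cycle_next[m.id] in available \
            else []
        pool = [x for x in available if x not in successors]
        extra = rng.choice(len(pool), size=max(n_succ - len(successors), 0),
                           replace=False)
        successors = sorted(successors + [pool[e] for e in extra])
        k = len(successors)
        if rng.random() < config.stereotyped_fraction and k >= 2:
            w = np.full(k, (1.0 - config.stereotyped_prob) / (k - 1))
            w[int(rng.integers(k))] = config.stereotyped_prob
        else:
            w = _draw_branch_row(rng, k, config.branch_uniform_mix,
                                 config.max_branch_prob)
        row = {sid: float(wi * (1.0 - end_prob))
               for sid, wi in zip(successors, w)}
        row[END] = float(end_prob)
        total = sum(row.values())
        row = {t: p / total for t, p in row.items()}
        branch[m.id] = row

    feature_model = None
    if config.with_features:
        feature_model = {lab: _draw_feature_params(rng)
                         for lab in sorted({l for m in motifs
                                            for l in m.labels})}
    gap_model = None
    if config.with_gaps:
        gap_model = {"within_motif": {"mu": math.log(10.0), "sigma": 0.4},
                     "between_motif": {"mu": math.log(60.0), "sigma": 0.5}}

    return Grammar(motifs=motifs, branch=branch,
                   bout_length_mean=config.bout_length_mean,
                   max_syllables=config.max_syllables,
                   feature_model=feature_model, gap_model=gap_model)


def _draw_feature_params(rng: np.random.Generator
                         ) -> dict[str, tuple[float, float]]:
    return {
        "mean_frequency_hz": (float(rng.uniform(2000, 6000)), 150.0 ** 2),
        "duration_ms": (float(rng.uniform(30, 200)), 8.0 ** 2),
        "spectrotemporal_entropy": (float(rng.uniform(0.3, 0.8)), 0.05 ** 2),
        "amplitude_entropy": (float(rng.uniform(0.3, 0.8)), 0.05 ** 2),
        "spectral_entropy": (float(rng.uniform(0.3, 0.8)), 0.05 ** 2),
    }


# ---------------------------------------------------------------------------
# pupil derivation


@dataclass
class LearningParams:
    """Parameters of the pupil-derivation (learning) model.

    Retention is logistic in log tutor prevalence, centered per level: an
    element of relative prevalence q within its level (motifs, branch
    transitions) is kept with probability
    sigmoid(retention_intercept + retention_slope * (ln q - mean ln q)),
    where the mean is over that level's elements.  The intercept thus
    sets the overall retention rate (0.5 ~ 62% retained) and a positive
    slope makes prevalent elements more likely to survive.  Retained
    branch rows are resampled from a Dirichlet centered on the tutor's
    probabilities with concentration ``transition_noise_kappa`` (infinite
    kappa copies them exactly).  Each retained multi-syllable motif is
    edited with probability ``edit_rate`` by a single-syllable addition
    (position drawn from ``addition_position_bias`` over beginning /
    middle / end insertion slots) or deletion (uniform over syllable
    slots); added labels are novel with probability
    ``novel_syllable_rate``, otherwise borrowed from another retained
    motif.  ``feature_jitter`` scales Gaussian drift of the pupil's
    per-label feature means in units of the feature SD.
    """

    retention_intercept: float = 0.5
    retention_slope: float = 1.5
    transition_noise_kappa: float = 60.0
    novel_syllable_rate: float = 0.3
    edit_rate: float = 0.6
    addition_fraction: float = 0.54
    addition_position_bias: tuple[float, float, float] = (0.55, 0.10, 0.35)
    feature_jitter: float = 0.1

    def validate(self) -> None:
        if self.transition_noise_kappa <= 0:
            raise ValueError("transition_noise_kappa must be > 0")
        for name in ("novel_syllable_rate", "edit_rate", "addition_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.addition_position_bias) - 1.0) > 1e-9:
            raise ValueError("addition_position_bias must sum to 1")


@dataclass
class EditLog:
    """Ground truth of a pupil derivation.

    Replaying the log onto the tutor grammar (``apply_edit_log``)
    reconstructs the pupil grammar's structure (motifs and branch
    matrix).
    """

    motifs_retained: list[str]
    motifs_dropped: list[str]
    motifs_novel: list[dict]
    motif_edits: dict[str, list[EditRecord]]  # tutor motif id -> edits
    pupil_motif_labels: dict[str, tuple[str, ...]]
    branch_updates: dict[str, dict[str, float]]
    syllables_retained: set[str] = field(default_factory=set)
    syllables_dropped: set[str] = field(default_factory=set)
    syllables_novel: set[str] = field(default_factory=set)
    transitions_retained: list[tuple[str, str]] = field(default_factory=list)
    transitions_dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def edits(self) -> list[EditRecord]:
        return [e for recs in self.motif_edits.values() for e in recs]


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def derive_pupil(tutor: Grammar, params: Optional[LearningParams] = None,
                 seed: int = 0) -> tuple[Grammar, EditLog]:
    """Derive a pupil grammar from a tutor under the learning model.

    Raises ``ValueError("degenerate pupil")`` when no motif survives.
    """
    params = params or LearningParams()
    params.validate()
    rng = np.random.default_rng(seed)
    pi = tutor.stationary_distribution()

    # ---- motif retention (prevalence-dependent) ------------------------
    log_pi_center = float(np.mean([math.log(pi[m.id])
                                   for m in tutor.motifs]))
    retained, dropped = [], []
    for m in tutor.motifs:
        p_keep = _sigmoid(params.retention_intercept + params.retention_slope
                          * (math.log(pi[m.id]) - log_pi_center))
        (retained if rng.random() < p_keep else dropped).append(m.id)
    if not retained:
        raise ValueError("degenerate pupil: no motif retained")

    # ---- novel motifs for a subset of dropped slots --------------------
    existing = {l for m in tutor.motifs for l in m.labels}
    novel_counter = 0

    def fresh_label() -> str:
        nonlocal novel_counter
        while True:
            lab = "n" + _label_name(novel_counter)
            novel_counter += 1
            if lab not in existing:
                existing.add(lab)
                return lab

    novel_motifs: list[GrammarMotif] = []
    for i, _ in enumerate(dropped):
        if rng.random() < params.novel_syllable_rate:
            length = int(rng.integers(2, 6))
            labels = tuple(fresh_label() for _ in range(length))
            novel_motifs.append(GrammarMotif(f"nm{i}", labels))

    # ---- single-syllable edits of retained motifs ----------------------
    motif_edits: dict[str, list[EditRecord]] = {}
    pupil_labels: dict[str, tuple[str, ...]] = {}
    retained_label_pool = sorted({l for mid in retained
                                  for l in tutor.motif_by_id(mid).labels})
    for mid in retained:
        m = tutor.motif_by_id(mid)
        pupil_labels[mid] = m.labels
        if m.is_repeat or rng.random() >= params.edit_rate:
            continue
        L = len(m.labels)
        can_add, can_del = L < 7, L > 2
        if not (can_add or can_del):
            continue
        do_add = can_add and (not can_del
                              or rng.random() < params.addition_fraction)
        if do_add:
            pos_class = ("beginning", "middle", "end")[
                int(rng.choice(3, p=list(params.addition_position_bias)))]
            if pos_class == "beginning":
                slot = 0
            elif pos_class == "end":
                slot = L
            else:
                slot = int(rng.integers(1, L))
            outside = [l for l in retained_label_pool if l not in m.labels]
            if rng.random() < params.novel_syllable_rate or not outside:
                lab = fresh_label()
            else:
                lab = outside[int(rng.integers(len(outside)))]
            new = m.labels[:slot] + (lab,) + m.labels[slot:]
            injected = EditRecord("addition", pos_class, lab, m.labels, new)
        else:
            slot = int(rng.integers(L))
            lab = m.labels[slot]
            new = m.labels[:slot] + m.labels[slot + 1:]
            injected = EditRecord("deletion", _slot_position(slot, L), lab,
                                  m.labels, new)
        pupil_labels[mid] = new
        # the log records the injected edit itself, so recovering it with
        # score_motif_edits stays an independent check
        motif_edits[mid] = [injected]

    # ---- branch rows over the pupil motif set --------------------------
    pupil_motifs = ([GrammarMotif(mid, pupil_labels[mid],
                                  tutor.motif_by_id(mid).repeat_mean)
                     for mid in retained] + novel_motifs)
    pupil_ids = [m.id for m in pupil_motifs]
    kappa = params.transition_noise_kappa
    trans_retained: list[tuple[str, str]] = []
    trans_dropped: list[tuple[str, str]] = []
    q_all = {(i, j): pi[i] * p
             for i in [m.id for m in tutor.motifs]
             for j, p in tutor.row_excluding_end(i).items()}
    q_total = sum(q_all.values())
    log_q_center = float(np.mean([math.log(q / q_total)
                                  for q in q_all.values()]))

    branch: dict[str, dict[str, float]] = {}
    for pm in pupil_motifs:
        successors = [x.id for x in pupil_motifs
                      if not (pm.is_repeat and x.id == pm.id)]
        if pm.id in retained:
            t_row = tutor.row_excluding_end(pm.id)
            end_p = tutor.branch[pm.id].get(END, 0.0)
            kept: dict[str, float] = {}
            ret_succ = [j for j in t_row if j in retained
                        and not (pm.is_repeat and j == pm.id)]
            if ret_succ:
                dominant = max(ret_succ, key=lambda j: (t_row[j], j))
                for j in ret_succ:
                    q = q_all[(pm.id, j)] / q_total
                    p_keep = _sigmoid(params.retention_intercept
                                      + params.retention_slope
                                      * (math.log(q) - log_q_center))
                    if j == dominant or rng.random() < p_keep:
                        kept[j] = t_row[j]
                        trans_retained.append((pm.id, j))
                    else:
                        trans_dropped.append((pm.id, j))
            trans_dropped.extend((pm.id, j) for j in t_row
                                 if j not in retained)
            novel_ids = [m.id for m in novel_motifs]
            if not kept and not novel_ids:
                raise ValueError("degenerate pupil: motif with no "
                                 "continuation")
            base = np.array([kept.get(j, 0.0) for j in successors])
            if base.sum() > 0:
                base = base / base.sum()
            alpha = np.array(
                [kappa * base[si] if successors[si] in kept
                 else (kappa * 0.05 if successors[si] in novel_ids else 0.0)
                 for si in range(len(successors))])
            active = alpha > 0
            if math.isinf(kappa):
                w = np.where([s in kept for s in successors], base, 0.0)
                w = w / w.sum()
            else:
                w = np.zeros(len(successors))
                w[active] = rng.dirichlet(alpha[active])
            row = {successors[si]: float(w[si] * (1.0 - end_p))
                   for si in range(len(successors)) if w[si] > 0}
            row[END] = end_p
        else:  # novel motif: uniform-ish continuation
            w = _draw_branch_row(rng, len(successors), mix=0.3, cap=0.95)
            mean_len = float(np.mean([m.expected_length
                                      for m in pupil_motifs]))
            end_p = min(mean_len / tutor.bout_length_mean, 0.5)
            row = {sid: float(wi * (1.0 - end_p))
                   for sid, wi in zip(successors, w)}
            row[END] = end_p
        total = sum(row.values())
        branch[pm.id] = {t: p / total for t, p in row.items()}

    # ---- feature / gap models ------------------------------------------
    feature_model = None
    if tutor.feature_model is not None:
        feature_model = {}
        for m in pupil_motifs:
            for lab in m.labels:
                if lab in feature_model:
                    continue
                if lab in tutor.feature_model:
                    feature_model[lab] = {
                        f: (mu + params.feature_jitter * math.sqrt(var)
                            * float(rng.standard_normal()), var)
                        for f, (mu, var) in tutor.feature_model[lab].items()}
                else:
                    feature_model[lab] = _draw_feature_params(rng)

    pupil = Grammar(motifs=pupil_motifs, branch=branch,
                    bout_length_mean=tutor.bout_length_mean,
                    max_syllables=tutor.max_syllables,
                    feature_model=feature_model,
                    gap_model=tutor.gap_model)

    tutor_labels = tutor.labels
    pupil_label_set = pupil.labels
    log = EditLog(
        motifs_retained=list(retained),
        motifs_dropped=list(dropped),
        motifs_novel=[{"id": m.id, "labels": list(m.labels),
                       "repeat_mean": m.repeat_mean} for m in novel_motifs],
        motif_edits=motif_edits,
        pupil_motif_labels=dict(pupil_labels),
        branch_updates={mid: dict(row) for mid, row in branch.items()},
        syllables_retained=tutor_labels & pupil_label_set,
        syllables_dropped=tutor_labels - pupil_label_set,
        syllables_novel=pupil_label_set - tutor_labels,
        transitions_retained=trans_retained,
        transitions_dropped=trans_dropped,
    )
    return pupil, log


def apply_edit_log(tutor: Grammar, log: EditLog) -> Grammar:
    """Replay an edit log onto the tutor grammar (structural replay).

    Reconstructs the pupil's motifs and branch matrix from the recorded
    retention decisions, motif edits, novel motifs and row updates; the
    result's structural signature equals the derived pupil's.
    """
    motifs = [GrammarMotif(mid, log.pupil_motif_labels[mid],
                           tutor.motif_by_id(mid).repeat_mean)
              for mid in log.motifs_retained]
    motifs += [GrammarMotif(d["id"], tuple(d["labels"]), d.get("repeat_mean"))
               for d in log.motifs_novel]
    return Grammar(motifs=motifs,
                   branch={mid: dict(row)
                           for mid, row in log.branch_updates.items()},
                   bout_length_mean=tutor.bout_length_mean,
                   max_syllables=tutor.max_syllables)


# ---------------------------------------------------------------------------
# corpus sampling


def sample_corpus(grammar: Grammar, n_bouts: int, seed: int = 0,
                  bird_id: str = "synthetic",
                  with_features: bool = True) -> SongCorpus:
    """Sample a corpus of bouts from a grammar; deterministic per seed.

    Each bout starts at a motif drawn from the stationary distribution of
    the END-conditioned branch chain, then chains motifs through the
    branch matrix until ``<END>`` is drawn or ``max_syllables`` is
    reached.  Repeat motifs expand to geometric run lengths.  When the
    grammar carries feature/gap models and ``with_features`` is true,
    every syllable gets feature draws and within-/between-motif gap
    durations.
    """
    if n_bouts < 1:
        raise ValueError("n_bouts must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [m.id for m in grammar.motifs]
    pi = grammar.stationary_distribution()
    start_p = np.array([pi[i] for i in ids])
    start_p = start_p / start_p.sum()
    rows = {mid: sorted(grammar.branch[mid].items())
            for mid in ids}
    row_targets = {mid: [t for t, _ in rows[mid]] for mid in ids}
    row_probs = {mid: np.array([p for _, p in rows[mid]]) for mid in ids}
    motif_map = {m.id: m for m in grammar.motifs}

    use_features = (with_features and grammar.feature_model is not None)
    use_gaps = (with_features and grammar.gap_model is not None)

    bouts = []
    for _ in range(n_bouts):
        labels: list[str] = []
        gap_class: list[Optional[str]] = []  # None | "within" | "between"
        mid = ids[int(rng.choice(len(ids), p=start_p))]
        while True:
            m = motif_map[mid]
            if m.is_repeat:
                run = int(rng.geometric(1.0 / m.repeat_mean))
                expansion = [m.labels[0]] * run
            else:
                expansion = list(m.labels)
            # the length cap ends the bout at a motif boundary so the cap
            # never leaves a partial motif in the corpus
            if labels and len(labels) + len(expansion) > grammar.max_syllables:
                break
            for k, lab in enumerate(expansion):
                if not labels:
                    gap_class.append(None)
                elif k == 0:
                    gap_class.append("between")
                else:
                    gap_class.append("within")
                labels.append(lab)
            if len(labels) >= grammar.max_syllables:
                break
            nxt = row_targets[mid][int(rng.choice(len(row_targets[mid]),
                                                  p=row_probs[mid]))]
            if nxt == END:
                break
            mid = nxt
        events = []
        for k, lab in enumerate(labels):
            gap = None
            if use_gaps and gap_class[k] is not None:
                gm = grammar.gap_model["within_motif" if gap_class[k] == "within"
                                       else "between_motif"]
                gap = float(rng.lognormal(gm["mu"], gm["sigma"]))
            features = None
            if use_features:
                fm = grammar.feature_model[lab]
                features = {f: float(rng.normal(mu, math.sqrt(var)))
                            for f, (mu, var) in fm.items()}
            events.append(SyllableEvent(lab, gap_before_ms=gap,
                                        features=features))
        bouts.append(Bout(tuple(events)))
    return SongCorpus(bird_id, bouts)
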