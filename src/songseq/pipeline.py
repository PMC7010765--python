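"""High-level pipeline: analyze one corpus, or compare a tutor-pupil pair.

The pipeline ties the modules together and writes the tidy CSV reports
used for downstream statistics (e.g. mixed-model fits, which are left to
the caller).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .corpus import SongCorpus
from . import compare as cmp
from .sequence_stats import (pairwise_transitions, repeat_number,
                             syllable_prevalence)
from .structure import classify_branch_points, discover_motifs


@dataclass
class RunConfig:
    """Thresholds and flags shared by the analysis entry points."""

    stereotypy_threshold: float = 0.95
    chain_threshold: float = 0.75
    motif_retention_threshold: float = 0.5
    min_count: int = 5
    min_transition_count: int = 1
    include_end: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("stereotypy_threshold", "chain_threshold",
                     "motif_retention_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


def analyze_corpus(corpus: SongCorpus,
                   config: Optional[RunConfig] = None) -> dict:
    """Single-bird structure report: prevalence, transitions, motifs,
    branch points, entropies, repeat numbers."""
    config = config or RunConfig()
    config.validate()
    prev = syllable_prevalence(corpus)
    trans = pairwise_transitions(corpus, include_end=config.include_end,
                                 min_count=config.min_transition_count)
    motifs = discover_motifs(corpus, chain_threshold=config.chain_threshold,
                             min_count=config.min_count)
    branch_points, stereotyped = classify_branch_points(
        corpus, motifs, stereotypy_threshold=config.stereotypy_threshold)
    repeats = {m.labels[0]: repeat_number(corpus, m.labels[0])
               for m in motifs if m.is_repeat}
    return {"prevalence": prev, "transitions": trans, "motifs": motifs,
            "branch_points": branch_points, "stereotyped": stereotyped,
            "repeat_numbers": repeats, "config": config}


def compare_corpora(tutor: SongCorpus, pupil: SongCorpus,
                    config: Optional[RunConfig] = None) -> dict:
    """Full tutor-pupil comparison across the four levels of sequencing."""
    config = config or RunConfig()
    t = analyze_corpus(tutor, config)
    p = analyze_corpus(pupil, config)
    rep = cmp.map_repertoire(tutor, pupil)
    motif_comps = cmp.match_motifs(
        t["motifs"], p["motifs"],
        threshold=config.motif_retention_threshold)
    bp_comps = [cmp.compare_branch_point(bp, motif_comps, p["branch_points"],
                                         p["stereotyped"])
                for bp in t["branch_points"]]
    edits = [e for c in motif_comps for e in c.edits]
    return {"tutor": t, "pupil": p, "repertoire": rep,
            "motif_comparisons": motif_comps,
            "branch_point_comparisons": bp_comps, "edits": edits,
            "predictors": _predictor_table(tutor, t, bp_comps),
            "config": config}


def _predictor_table(tutor_corpus: SongCorpus, tutor_report: dict,
                     bp_comps) -> pd.DataFrame:
    """Tidy per-transition table: gap duration vs copying fidelity.

    One row per tutor branch-point transition with the mean gap duration
    before the transition syllable (NaN when the corpus has no gap
    annotations), whether the pupil retained it, and the absolute
    difference in transition probability — inputs for external
    mixed-model fits.
    """
    gap_sums: dict[tuple[str, str], list[float]] = {}
    for bout in tutor_corpus.bouts:
        for prv, ev in zip(bout.events, bout.events[1:]):
            if ev.gap_before_ms is not None:
                gap_sums.setdefault((prv.label, ev.label), []).append(
                    ev.gap_before_ms)
    rows = []
    for comp in bp_comps:
        bp = comp.tutor_bp
        last = bp.sequence.labels[-1]
        for nxt, p_t in sorted(bp.transitions.items()):
            gaps = gap_sums.get((last, nxt), [])
            retained = nxt in comp.retained_transitions
            rows.append({
                "branch_sequence": " ".join(bp.sequence.labels),
                "transition": nxt,
                "tutor_prob": p_t,
                "gap_mean_ms": float(np.mean(gaps)) if gaps else float("nan"),
                "retained": retained,
                "status": comp.status,
            })
    return pd.DataFrame(rows, columns=["branch_sequence", "transition",
                                       "tutor_prob", "gap_mean_ms",
                                       "retained", "status"])


# ---------------------------------------------------------------------------
# report writers


def write_analysis_reports(report: dict, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    prev = report["prevalence"]
    df = pd.DataFrame([{"label": l, "count": prev.counts[l],
                        "fraction": prev.fractions[l]}
                       for l in sorted(prev.counts)])
    written.append(_write(df, outdir / "prevalence.csv"))

    trans = report["transitions"]
    rows = [{"context": " ".join(ctx), "next": nxt,
             "count": trans.counts[ctx].get(nxt, 0), "prob": p}
            for ctx in sorted(trans.probabilities)
            for nxt, p in sorted(trans.probabilities[ctx].items())]
    written.append(_write(pd.DataFrame(
        rows, columns=["context", "next", "count", "prob"]),
        outdir / "transitions.csv"))

    mrows = [{"motif": str(m), "count": m.count,
              "rel_prevalence": m.relative_prevalence,
              "is_repeat": m.is_repeat} for m in report["motifs"]]
    written.append(_write(pd.DataFrame(
        mrows, columns=["motif", "count", "rel_prevalence", "is_repeat"]),
        outdir / "motifs.csv"))

    brows = [{"sequence": str(bp.sequence), "next": nxt, "prob": p,
              "entropy_bits": bp.entropy_bits, "n_obs": bp.n_obs}
             for bp in report["branch_points"]
             for nxt, p in sorted(bp.transitions.items())]
    written.append(_write(pd.DataFrame(
        brows, columns=["sequence", "next", "prob", "entropy_bits", "n_obs"]),
        outdir / "branch_points.csv"))

    erows = [{"context": " ".join(bp.sequence.labels),
              "entropy_bits": bp.entropy_bits, "n_obs": bp.n_obs}
             for bp in report["branch_points"]]
    written.append(_write(pd.DataFrame(
        erows, columns=["context", "entropy_bits", "n_obs"]),
        outdir / "entropy.csv"))
    return written


def write_comparison_reports(result: dict, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    rep = result["repertoire"]
    rrows = ([{"label": l, "status": "retained"} for l in sorted(rep.retained)]
             + [{"label": l, "status": "dropped"} for l in sorted(rep.dropped)]
             + [{"label": l, "status": "novel"} for l in sorted(rep.novel)])
    written.append(_write(pd.DataFrame(rrows, columns=["label", "status"]),
                          outdir / "repertoire.csv"))

    mrows = [{"tutor_motif": " ".join(c.tutor_motif.labels),
              "status": c.status,
              "pupil_motif": (" ".join(c.best_pupil_motif.labels)
                              if c.best_pupil_motif else ""),
              "shared_fraction": c.shared_fraction}
             for c in result["motif_comparisons"]]
    written.append(_write(pd.DataFrame(
        mrows, columns=["tutor_motif", "status", "pupil_motif",
                        "shared_fraction"]), outdir / "motifs.csv"))

    erows = [asdict(e) | {"tutor_motif": " ".join(e.tutor_motif),
                          "pupil_motif": " ".join(e.pupil_motif)}
             for e in result["edits"]]
    written.append(_write(pd.DataFrame(
        erows, columns=["type", "position", "label", "tutor_motif",
                        "pupil_motif"]), outdir / "edits.csv"))

    brows = [{"sequence": " ".join(c.tutor_bp.sequence.labels),
              "status": c.status,
              "n_retained": len(c.retained_transitions),
              "n_dropped": len(c.dropped_transitions),
              "n_novel": len(c.novel_transitions),
              "total_deviation_pct": c.total_deviation_pct,
              "dominant_match": c.dominant_match,
              "entropy_tutor": c.entropy_tutor,
              "entropy_pupil": c.entropy_pupil}
             for c in result["branch_point_comparisons"]]
    written.append(_write(pd.DataFrame(
        brows, columns=["sequence", "status", "n_retained", "n_dropped",
                        "n_novel", "total_deviation_pct", "dominant_match",
                        "entropy_tutor", "entropy_pupil"]),
        outdir / "branch_points.csv"))

    written.append(_write(result["predictors"], outdir / "predictors.csv"))
    return written


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False)
    return path
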