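"""Reading and writing corpora, grammars, and feature tables.

Formats (all plain text, UTF-8, case-sensitive labels):

* bout files (``.bouts``): one bout per line, labels separated by
  whitespace;
* gap/feature CSV: header ``bout,pos,gap_before_ms,<feature names...>``
  with 0-based bout index and 0-based within-bout position; an empty
  ``gap_before_ms`` cell means the gap is absent (conventionally the first
  syllable of a bout);
* grammar JSON: see :mod:`songseq.grammar`.
"""

from __future__ import annotations

import csv
import json
import os
from pathlib import Path
from typing import Optional, Union

from .corpus import RESERVED_TOKENS, Bout, SongCorpus, SyllableEvent
from .grammar import Grammar

PathLike = Union[str, os.PathLike]


def read_corpus(path: PathLike,
                feature_path: Optional[PathLike] = None,
                bird_id: Optional[str] = None) -> SongCorpus:
    """Read a bout file (and optional gap/feature CSV) into a corpus.

    Raises ``ValueError`` on an empty file, a reserved token, or a CSV row
    keyed to a nonexistent (bout, position).
    """
    path = Path(path)
    label_bouts: list[list[str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            labels = line.split()
            if not labels:
                continue
            for lab in labels:
                if lab in RESERVED_TOKENS:
                    raise ValueError(
                        f"{path}:{lineno}: reserved token {lab!r} in bout file")
            label_bouts.append(labels)
    if not label_bouts:
        raise ValueError(f"empty corpus: {path}")

    gaps: dict[tuple[int, int], float] = {}
    feats: dict[tuple[int, int], dict[str, float]] = {}
    if feature_path is not None:
        gaps, feats = _read_feature_csv(feature_path, label_bouts)

    bouts = []
    for bi, labels in enumerate(label_bouts):
        events = []
        for pos, lab in enumerate(labels):
            events.append(SyllableEvent(
                label=lab,
                gap_before_ms=gaps.get((bi, pos)),
                features=feats.get((bi, pos))))
        bouts.append(Bout(tuple(events)))
    return SongCorpus(bird_id or path.stem, bouts)


def _read_feature_csv(feature_path: PathLike,
                      label_bouts: list[list[str]]):
    gaps: dict[tuple[int, int], float] = {}
    feats: dict[tuple[int, int], dict[str, float]] = {}
    with Path(feature_path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or reader.fieldnames[:2] != ["bout", "pos"]:
            raise ValueError(
                f"{feature_path}: feature CSV must start with 'bout,pos' columns")
        feature_names = [c for c in reader.fieldnames
                         if c not in ("bout", "pos", "gap_before_ms")]
        for row in reader:
            bi, pos = int(row["bout"]), int(row["pos"])
            if bi >= len(label_bouts) or pos >= len(label_bouts[bi]):
                raise ValueError(
                    f"{feature_path}: row (bout={bi}, pos={pos}) references a "
                    "nonexistent position")
            gap = row.get("gap_before_ms", "")
            if gap not in ("", None):
                gaps[(bi, pos)] = float(gap)
            if feature_names:
                feats[(bi, pos)] = {f: float(row[f]) for f in feature_names}
    return gaps, feats


def write_corpus(corpus: SongCorpus, path: PathLike) -> None:
    """Write one bout per line, single-space separated. Deterministic."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for bout in corpus.bouts:
            fh.write(" ".join(bout.labels) + "\n")


def write_features(corpus: SongCorpus, path: PathLike) -> None:
    """Write the gap/feature CSV companion to a bout file.

    Only events carrying a gap or features produce a row.
    """
    names = corpus.feature_names or ()
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bout", "pos", "gap_before_ms", *names])
        for bi, bout in enumerate(corpus.bouts):
            for pos, ev in enumerate(bout.events):
                if ev.gap_before_ms is None and ev.features is None:
                    continue
                gap = "" if ev.gap_before_ms is None else repr(ev.gap_before_ms)
                fvals = [repr(ev.features[n]) for n in names] if ev.features else \
                        [""] * len(names)
                writer.writerow([bi, pos, gap, *fvals])


def read_grammar(path: PathLike) -> Grammar:
    """Read and validate a grammar JSON file."""
    with Path(path).open("r", encoding="utf-8") as fh:
        data = json.load(fh)
    return Grammar.from_dict(data)


def write_grammar(grammar: Grammar, path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(grammar.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
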