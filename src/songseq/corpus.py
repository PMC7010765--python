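"""Core containers for labelled song corpora.

A Bengalese finch song bout is a sequence of discrete syllables; here each
syllable is a symbolic label optionally annotated with the silent gap that
preceded it (ms) and a vector of named acoustic features.  A
:class:`SongCorpus` is one bird's set of bouts and is the unit of analysis
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

START = "<START>"
END = "<END>"
RESERVED_TOKENS = frozenset({START, END})


@dataclass(frozen=True)
class SyllableEvent:
    """One syllable rendition: a label plus optional gap/feature annotations.

    ``gap_before_ms`` is the silent interval between this syllable and the
    previous one within the bout; it is absent (``None``) for the first
    syllable of a bout, which has no preceding within-bout gap.
    """

    label: str
    gap_before_ms: Optional[float] = None
    features: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if not self.label or any(c.isspace() for c in self.label):
            raise ValueError(f"invalid syllable label {self.label!r}")
        if self.label in RESERVED_TOKENS:
            raise ValueError(f"label {self.label!r} is a reserved token")
        if self.gap_before_ms is not None and self.gap_before_ms < 0:
            raise ValueError("gap_before_ms must be nonnegative")


@dataclass(frozen=True)
class Bout:
    """An ordered, non-empty sequence of syllable events."""

    events: tuple[SyllableEvent, ...]

    def __post_init__(self) -> None:
        if len(self.events) == 0:
            raise ValueError("a bout must contain at least one syllable")

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "Bout":
        return cls(tuple(SyllableEvent(l) for l in labels))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.events)

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class SongCorpus:
    """A bird's recorded song: an identifier plus a list of bouts."""

    bird_id: str
    bouts: list[Bout] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.bouts) == 0:
            raise ValueError("empty corpus")

    @classmethod
    def from_label_lists(cls, bird_id: str,
                         bouts: Sequence[Sequence[str]]) -> "SongCorpus":
        return cls(bird_id, [Bout.from_labels(b) for b in bouts])

    @property
    def bout_labels(self) -> list[tuple[str, ...]]:
        return [b.labels for b in self.bouts]

    @property
    def repertoire(self) -> set[str]:
        return {e.label for b in self.bouts for e in b.events}

    @property
    def n_syllables(self) -> int:
        return sum(len(b) for b in self.bouts)

    @property
    def feature_names(self) -> Optional[tuple[str, ...]]:
        """The shared ordered feature-name set, or None if no features."""
        for b in self.bouts:
            for e in b.events:
                if e.features is not None:
                    return tuple(e.features.keys())
        return None
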