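"""Domain types for valence-conditioned free-recall analysis.

The analysis tracks how participants move through memory while freely
recalling affective word lists: which valence category (positive, negative,
neutral) recall starts from, whether consecutive recalls stay within a
category or switch, and on which category recall stops.  These types carry
the presented stimulus lists, the scored recall sequences of a two-arm
(MBCT vs. wait-list control), two-timepoint (T1/T2) trial, and the pooled
estimates and permutation results the analysis produces.

Counts are kept alongside every pooled probability (numerator/denominator)
so that estimates are exactly recomputable and poolable.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Optional

CATEGORIES = ("positive", "negative", "neutral")
TIMEPOINTS = ("T1", "T2")
GROUPS = ("MBCT", "control")
#: pooled metrics: start / stay / stop-hazard / terminal-share / percent recalled
METRICS = ("pstart", "pstay", "pstop", "terminal", "recall_pct")
CLASSIFICATIONS = ("target", "buffer", "intrusion", "repetition")

_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def normalize_word(word: str) -> str:
    """Canonical word form: lowercased, trimmed, ASCII punctuation stripped.

    Matching between recalled and presented words is exact on this form; no
    stemming or fuzzy matching is attempted, which keeps scoring reproducible.
    """
    return str(word).strip().lower().translate(_PUNCT_TABLE)


@dataclass(frozen=True)
class WordNorm:
    """Normative affective ratings for one word (ANEW-style).

    valence/arousal are on the 1-9 self-assessment-manikin scale, frequency
    is occurrences per million, length is the character count.
    """

    word: str
    valence: float
    arousal: float
    frequency: float
    length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "word", normalize_word(self.word))
        if not self.word:
            raise ValueError("word normalizes to the empty string")
        if not (1.0 <= self.valence <= 9.0):
            raise ValueError(f"valence {self.valence} outside [1, 9]")
        if not (1.0 <= self.arousal <= 9.0):
            raise ValueError(f"arousal {self.arousal} outside [1, 9]")
        if self.frequency < 0:
            raise ValueError("frequency must be nonnegative")
        if self.length < 1:
            raise ValueError("length must be >= 1")


@dataclass(frozen=True)
class ListItem:
    """One presented word: serial position, valence category, buffer flag."""

    word: str
    serial_position: int
    category: str
    is_buffer: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "word", normalize_word(self.word))
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.serial_position < 1:
            raise ValueError("serial_position is 1-based")
        if self.is_buffer and self.category != "neutral":
            raise ValueError("buffer items must be neutral")


@dataclass(frozen=True)
class StimulusList:
    """An ordered word list as presented to a participant.

    Only structural invariants (contiguous serial positions, no duplicate
    words) are enforced here; composition and ordering constraints of the
    default 22-word design live in :mod:`recalldyn.list_builder`, so that
    non-standard lists (e.g. large depletion-free simulation lists) remain
    representable.
    """

    list_id: str
    items: tuple[ListItem, ...]
    modality: str = "visual"  # informational only; analyses collapse lists

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        positions = [it.serial_position for it in self.items]
        if positions != list(range(1, len(self.items) + 1)):
            raise ValueError(
                f"list {self.list_id!r}: serial positions must be 1..N contiguous"
            )
        words = [it.word for it in self.items]
        if len(set(words)) != len(words):
            raise ValueError(f"list {self.list_id!r}: duplicate words")
        if self.modality not in ("visual", "aural"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def targets(self) -> tuple[ListItem, ...]:
        return tuple(it for it in self.items if not it.is_buffer)

    @property
    def buffers(self) -> tuple[ListItem, ...]:
        return tuple(it for it in self.items if it.is_buffer)

    @cached_property
    def _by_word(self) -> dict[str, ListItem]:
        return {it.word: it for it in self.items}

    def category_of(self, word: str) -> Optional[str]:
        """Valence category of a (normalized) word, or None if not on the list."""
        item = self._by_word.get(word)
        return None if item is None else item.category

    def is_buffer_word(self, word: str) -> bool:
        item = self._by_word.get(word)
        return item is not None and item.is_buffer

    def target_count(self, category: str) -> int:
        return sum(1 for it in self.targets if it.category == category)


@dataclass(frozen=True)
class RecallEvent:
    """One recalled word, classified against the studied list.

    classification: ``target`` (first recall of a studied non-buffer word),
    ``buffer`` (first recall of an edge buffer), ``repetition`` (a studied
    word recalled again), or ``intrusion`` (a word not on the list).
    category is carried only for target/buffer events.
    """

    output_position: int
    raw_word: str
    classification: str
    category: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "raw_word", normalize_word(self.raw_word))
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")
        has_cat = self.category is not None
        needs_cat = self.classification in ("target", "buffer")
        if has_cat != needs_cat:
            raise ValueError(
                "category must be present iff classification is target/buffer"
            )
        if has_cat and self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.output_position < 1:
            raise ValueError("output_position is 1-based")


@dataclass(frozen=True)
class RecallSequence:
    """Ordered recall output of one participant for one list at one timepoint."""

    participant_id: str
    timepoint: str
    list_id: str
    events: tuple[RecallEvent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        positions = [e.output_position for e in self.events]
        if positions != list(range(1, len(self.events) + 1)):
            raise ValueError("output positions must be 1..N contiguous")


@dataclass(frozen=True)
class ParticipantRecord:
    """All recall sequences of one participant, with their arm assignment."""

    participant_id: str
    group: str
    sequences: tuple[RecallSequence, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        for seq in self.sequences:
            if seq.participant_id != self.participant_id:
                raise ValueError(
                    f"sequence participant {seq.participant_id!r} != "
                    f"record participant {self.participant_id!r}"
                )

    def sequences_at(self, timepoint: str) -> tuple[RecallSequence, ...]:
        return tuple(s for s in self.sequences if s.timepoint == timepoint)


@dataclass(frozen=True)
class StudyDataset:
    """The full trial: participants x (group, timepoint) x lists.

    This is the unit on which estimates are pooled and labels permuted.
    """

    participants: tuple[ParticipantRecord, ...]
    lists: dict[str, StimulusList] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "participants", tuple(self.participants))
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate participant ids")
        for lid, stim in self.lists.items():
            if stim.list_id != lid:
                raise ValueError(f"lists key {lid!r} != list_id {stim.list_id!r}")
        from .errors import ReferentialIntegrityError

        for p in self.participants:
            for seq in p.sequences:
                if seq.list_id not in self.lists:
                    raise ReferentialIntegrityError(
                        f"sequence of participant {p.participant_id!r} references "
                        f"unknown list {seq.list_id!r}"
                    )

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def participants_in(self, group: str) -> tuple[ParticipantRecord, ...]:
        return tuple(p for p in self.participants if p.group == group)

    def sequences_in_cell(self, group: str, timepoint: str) -> list[RecallSequence]:
        """All sequences of a (group, timepoint) design cell."""
        out: list[RecallSequence] = []
        for p in self.participants:
            if p.group == group:
                out.extend(p.sequences_at(timepoint))
        return out

    def stimulus_for(self, seq: RecallSequence) -> StimulusList:
        return self.lists[seq.list_id]


@dataclass(frozen=True)
class DynamicsEstimate:
    """One pooled estimate with its exact counts.

    ``value`` is numerator/denominator, scaled to percent for recall_pct.
    Counts are pooled over all lists and participants of the cell before
    division (event-level pooling), never averaged per participant.
    """

    metric: str
    category: str
    group: str
    timepoint: str
    numerator: int
    denominator: int
    value: float

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError("numerator must lie in [0, denominator]")
        scale = 100.0 if self.metric == "recall_pct" else 1.0
        expected = scale * self.numerator / self.denominator
        if abs(self.value - expected) > 1e-9:
            raise ValueError("value inconsistent with counts")

    @classmethod
    def from_counts(
        cls,
        metric: str,
        category: str,
        group: str,
        timepoint: str,
        numerator: int,
        denominator: int,
    ) -> "DynamicsEstimate":
        scale = 100.0 if metric == "recall_pct" else 1.0
        return cls(
            metric=metric,
            category=category,
            group=group,
            timepoint=timepoint,
            numerator=int(numerator),
            denominator=int(denominator),
            value=scale * numerator / denominator,
        )


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of one permutation (or exact enumeration) test."""

    metric: str
    category: str
    effect: str  # "time_within_group" or "interaction"
    observed_stat: float
    n_perm: int
    p_value: float
    sidedness: str = "two_sided"
    group: Optional[str] = None  # set for time_within_group
    seed: Optional[int] = None  # None for exact enumeration
    null_mean: float = 0.0
    null_sd: float = 0.0
    n_redrawn: int = 0
    method: str = "monte_carlo"

    def __post_init__(self) -> None:
        if self.effect not in ("time_within_group", "interaction"):
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.sidedness not in ("two_sided", "greater", "less"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "category": self.category,
            "effect": self.effect,
            "group": self.group,
            "observed_stat": self.observed_stat,
            "n_perm": self.n_perm,
            "p_value": self.p_value,
            "sidedness": self.sidedness,
            "seed": self.seed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "n_redrawn": self.n_redrawn,
            "method": self.method,
        }


def norms_by_word(norms: Iterable[WordNorm]) -> dict[str, WordNorm]:
    """Index a norms table by word, enforcing uniqueness."""
    from .errors import DuplicateRowError

    out: dict[str, WordNorm] = {}
    for n in norms:
        if n.word in out:
            raise DuplicateRowError(f"word {n.word!r} appears twice in norms table")
        out[n.word] = n
    return out
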