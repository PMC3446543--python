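"""Scoring of raw recall transcripts against the studied list.

Each recalled word is classified in output order: the first occurrence of a
studied non-buffer word is a ``target`` (with its valence category), the
first occurrence of an edge buffer is a ``buffer``, any later occurrence of
an already-recalled studied word is a ``repetition``, and anything not on
the list is an ``intrusion``.  All dynamics are computed on the *retained*
sequence — target events only — so buffers, intrusions and repetitions are
jumped over when transitions are counted, the standard practice in free
recall analysis.  Matching is exact after normalization (lowercase, trimmed,
ASCII punctuation stripped); no spelling correction is attempted.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .data_model import (
    RecallEvent,
    RecallSequence,
    StimulusList,
    normalize_word,
)


def score_recall_sequence(
    raw_words: Iterable[str],
    stim: StimulusList,
    participant_id: str,
    timepoint: str,
    list_id: Optional[str] = None,
) -> RecallSequence:
    """Classify an ordered transcript of recalled words.

    Any string input is classifiable; an empty transcript yields a sequence
    with zero events.  Scoring is deterministic and idempotent: rescoring
    the raw words of a scored sequence reproduces it exactly.
    """
    if list_id is None:
        list_id = stim.list_id
    seen: set[str] = set()
    events: list[RecallEvent] = []
    for pos, raw in enumerate(raw_words, start=1):
        word = normalize_word(raw)
        category = stim.category_of(word)
        if category is None:
            ev = RecallEvent(pos, word, "intrusion")
        elif word in seen:
            ev = RecallEvent(pos, word, "repetition")
        else:
            seen.add(word)
            cls = "buffer" if stim.is_buffer_word(word) else "target"
            ev = RecallEvent(pos, word, cls, category)
        events.append(ev)
    return RecallSequence(participant_id, timepoint, list_id, tuple(events))


def retained_category_sequence(seq: RecallSequence) -> tuple[str, ...]:
    """Ordered valence categories of the target events only.

    Buffer, intrusion and repetition events are removed; the result may be
    empty.  This is the sequence on which Pstart, Pstay and Pstop operate.
    """
    return tuple(
        e.category  # type: ignore[misc]
        for e in seq.events
        if e.classification == "target"
    )


def raw_word_sequence(seq: RecallSequence) -> tuple[str, ...]:
    """The transcript back out of a scored sequence (for round-tripping)."""
    return tuple(e.raw_word for e in seq.events)
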