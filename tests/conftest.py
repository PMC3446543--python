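"""Shared fixtures: hand-buildable datasets with prescribed category sequences."""

from __future__ import annotations

import numpy as np
import pytest

from recalldyn.data_model import (
    CATEGORIES,
    ListItem,
    ParticipantRecord,
    RecallEvent,
    RecallSequence,
    StimulusList,
    StudyDataset,
)
from recalldyn.synthetic_data import composition_stimulus_list


@pytest.fixture
def shared_stim() -> StimulusList:
    """Ten targets per category, no buffers; enough for any short sequence."""
    return composition_stimulus_list(10, list_id="X")


def sequence_from_categories(
    cats, stim: StimulusList, participant_id: str, timepoint: str, list_id=None
) -> RecallSequence:
    """A scored sequence whose retained categories equal ``cats`` exactly.

    Distinct words of each category are consumed in list order, so up to
    ten recalls per category per sequence are supported.
    """
    words_by_cat = {
        c: [it.word for it in stim.targets if it.category == c] for c in CATEGORIES
    }
    used = {c: 0 for c in CATEGORIES}
    events = []
    for pos, c in enumerate(cats, start=1):
        word = words_by_cat[c][used[c]]
        used[c] += 1
        events.append(RecallEvent(pos, word, "target", c))
    return RecallSequence(
        participant_id, timepoint, list_id or stim.list_id, tuple(events)
    )


def dataset_from_cells(
    cells: dict, stim: StimulusList | None = None
) -> StudyDataset:
    """Build a dataset from {(group, timepoint): [category-sequence, ...]}.

    One participant per group carries all of that group's lists; intended
    for metric-level tests (not for I/O round-trips, where list ids must
    disambiguate sequences).
    """
    stim = stim or composition_stimulus_list(10, list_id="X")
    by_group: dict[str, list[RecallSequence]] = {}
    for (group, tp), seq_cats in cells.items():
        pid = f"p-{group}"
        for cats in seq_cats:
            by_group.setdefault(group, []).append(
                sequence_from_categories(cats, stim, pid, tp)
            )
    participants = tuple(
        ParticipantRecord(f"p-{g}", g, tuple(seqs)) for g, seqs in sorted(by_group.items())
    )
    return StudyDataset(participants, {stim.list_id: stim})


def random_participant_dataset(
    rng: np.random.Generator,
    n_participants: int = 6,
    n_lists: int = 2,
    max_len: int = 5,
    n_mbct: int | None = None,
) -> StudyDataset:
    """Random multi-participant dataset with iid category draws per recall."""
    stim = composition_stimulus_list(max(6, max_len), list_id="X")
    if n_mbct is None:
        n_mbct = max(1, n_participants // 2)
    participants = []
    for i in range(n_participants):
        pid = f"P{i:02d}"
        group = "MBCT" if i < n_mbct else "control"
        seqs = []
        for tp in ("T1", "T2"):
            for _ in range(n_lists):
                length = int(rng.integers(0, max_len + 1))
                cats = [CATEGORIES[int(rng.integers(3))] for _ in range(length)]
                seqs.append(sequence_from_categories(cats, stim, pid, tp))
        participants.append(ParticipantRecord(pid, group, tuple(seqs)))
    return StudyDataset(tuple(participants), {stim.list_id: stim})


@pytest.fixture
def micro_stim() -> StimulusList:
    """Tiny hand-built list: buffers at the edges, two targets in between."""
    items = (
        ListItem("calm", 1, "neutral", is_buffer=True),
        ListItem("misery", 2, "negative"),
        ListItem("sunshine", 3, "positive"),
        ListItem("chair", 4, "neutral"),
        ListItem("quiet", 5, "neutral", is_buffer=True),
    )
    return StimulusList("micro", items)
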