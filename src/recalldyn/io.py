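"""CSV/JSON interchange for datasets, norms, estimates and test results.

Formats (comma-separated, UTF-8, header row required):

* events CSV:  participant_id, group, timepoint, list_id, output_position, word
* lists CSV:   list_id, serial_position, word, category, is_buffer (0/1),
  plus an optional modality column (informational; defaults to visual)
* norms CSV:   word, valence, arousal, frequency, length
* scored CSV:  events columns + classification, category
* estimates CSV: metric, category, group, timepoint, numerator, denominator, value
* results JSON: array of permutation-result objects

Loading validates labels strictly (unknown categories, groups or timepoints
raise schema errors; nothing is silently coerced), re-scores recall events
against the stimulus lists, and sorts rows deterministically, so
``load_study(write_study(d))`` reproduces ``d`` field by field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .data_model import (
    CATEGORIES,
    DynamicsEstimate,
    GROUPS,
    ListItem,
    ParticipantRecord,
    PermutationResult,
    StimulusList,
    StudyDataset,
    TIMEPOINTS,
    WordNorm,
    normalize_word,
)
from .errors import (
    DuplicateRowError,
    ReferentialIntegrityError,
    SchemaError,
)

PathLike = Union[str, Path]

EVENTS_COLUMNS = (
    "participant_id",
    "group",
    "timepoint",
    "list_id",
    "output_position",
    "word",
)
LISTS_COLUMNS = ("list_id", "serial_position", "word", "category", "is_buffer")
NORMS_COLUMNS = ("word", "valence", "arousal", "frequency", "length")
ESTIMATES_COLUMNS = (
    "metric",
    "category",
    "group",
    "timepoint",
    "numerator",
    "denominator",
    "value",
)


def _read_csv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def load_norms(path: PathLike) -> list[WordNorm]:
    """Read an ANEW-style word-norms table."""
    df = _read_csv(path, NORMS_COLUMNS)
    norms: list[WordNorm] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        try:
            norm = WordNorm(
                word=row.word,
                valence=float(row.valence),
                arousal=float(row.arousal),
                frequency=float(row.frequency),
                length=int(row.length),
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: invalid norms row {row!r}: {exc}") from exc
        if norm.word in seen:
            raise DuplicateRowError(f"{path}: duplicate word {norm.word!r}")
        seen.add(norm.word)
        norms.append(norm)
    return norms


def write_norms(norms: Iterable[WordNorm], path: PathLike) -> None:
    df = pd.DataFrame(
        [(n.word, n.valence, n.arousal, n.frequency, n.length) for n in norms],
        columns=list(NORMS_COLUMNS),
    )
    df.to_csv(path, index=False, lineterminator="\n")


def load_lists(path: PathLike) -> dict[str, StimulusList]:
    """Read stimulus-list definitions."""
    df = _read_csv(path, LISTS_COLUMNS)
    has_modality = "modality" in df.columns
    lists: dict[str, StimulusList] = {}
    for list_id, sub in df.groupby("list_id", sort=True):
        sub = sub.copy()
        try:
            sub["serial_position"] = sub["serial_position"].astype(int)
        except ValueError as exc:
            raise SchemaError(f"{path}: non-integer serial_position") from exc
        sub = sub.sort_values("serial_position")
        items = []
        for row in sub.itertuples(index=False):
            if row.category not in CATEGORIES:
                raise SchemaError(
                    f"{path}: unknown category {row.category!r} in list {list_id!r}"
                )
            if row.is_buffer not in ("0", "1"):
                raise SchemaError(
                    f"{path}: is_buffer must be 0 or 1, got {row.is_buffer!r}"
                )
            try:
                items.append(
                    ListItem(
                        word=row.word,
                        serial_position=row.serial_position,
                        category=row.category,
                        is_buffer=row.is_buffer == "1",
                    )
                )
            except ValueError as exc:
                raise SchemaError(f"{path}: invalid list row: {exc}") from exc
        modality = str(sub["modality"].iloc[0]) if has_modality else "visual"
        try:
            lists[str(list_id)] = StimulusList(str(list_id), tuple(items), modality)
        except ValueError as exc:
            raise SchemaError(f"{path}: invalid list {list_id!r}: {exc}") from exc
    return lists


def load_study(events_path: PathLike, lists_path: PathLike) -> StudyDataset:
    """Read and validate a full study dataset.

    Words are normalized and recall events re-scored against the stimulus
    lists; rows are sorted by output/serial position.  Schema violations
    raise :class:`SchemaError` subclasses naming the offending column/value.
    """
    from .recall_scoring import score_recall_sequence

    lists = load_lists(lists_path)
    df = _read_csv(events_path, EVENTS_COLUMNS)
    try:
        df["output_position"] = df["output_position"].astype(int)
    except ValueError as exc:
        raise SchemaError(f"{events_path}: non-integer output_position") from exc

    for col, allowed in (("group", GROUPS), ("timepoint", TIMEPOINTS)):
        bad = set(df[col]) - set(allowed)
        if bad:
            raise SchemaError(
                f"{events_path}: invalid {col} value(s) {sorted(bad)!r}"
            )
    unknown = set(df["list_id"]) - set(lists)
    if unknown:
        raise ReferentialIntegrityError(
            f"{events_path}: events reference unknown list(s) {sorted(unknown)!r}"
        )
    dup = df.duplicated(
        subset=["participant_id", "timepoint", "list_id", "output_position"]
    )
    if dup.any():
        row = df[dup].iloc[0]
        raise DuplicateRowError(
            f"{events_path}: duplicate (participant, timepoint, list, position) "
            f"row: {tuple(row[k] for k in ('participant_id', 'timepoint', 'list_id', 'output_position'))}"
        )

    participants: list[ParticipantRecord] = []
    for pid, pdf in df.groupby("participant_id", sort=True):
        groups = set(pdf["group"])
        if len(groups) > 1:
            raise SchemaError(
                f"{events_path}: participant {pid!r} has conflicting group "
                f"labels {sorted(groups)!r}"
            )
        sequences = []
        for (tp, lid), sdf in pdf.groupby(["timepoint", "list_id"], sort=True):
            sdf = sdf.sort_values("output_position")
            positions = list(sdf["output_position"])
            if positions != list(range(1, len(positions) + 1)):
                raise SchemaError(
                    f"{events_path}: participant {pid!r} {tp} {lid}: output "
                    "positions must be 1..N contiguous"
                )
            raw = [normalize_word(w) for w in sdf["word"]]
            sequences.append(
                score_recall_sequence(raw, lists[str(lid)], str(pid), str(tp))
            )
        participants.append(
            ParticipantRecord(str(pid), groups.pop(), tuple(sequences))
        )
    return StudyDataset(tuple(participants), lists)


def write_study(
    data: StudyDataset, events_path: PathLike, lists_path: PathLike
) -> None:
    """Write the two CSVs in the schema accepted by :func:`load_study`.

    Row order is deterministic: events by (participant, timepoint, list,
    position), lists by (list, serial position).  An empty dataset yields
    headers-only files.
    """
    event_rows = []
    for p in sorted(data.participants, key=lambda p: p.participant_id):
        for seq in sorted(p.sequences, key=lambda s: (s.timepoint, s.list_id)):
            for e in seq.events:
                event_rows.append(
                    (
                        p.participant_id,
                        p.group,
                        seq.timepoint,
                        seq.list_id,
                        e.output_position,
                        e.raw_word,
                    )
                )
    pd.DataFrame(event_rows, columns=list(EVENTS_COLUMNS)).to_csv(
        events_path, index=False, lineterminator="\n"
    )
    list_rows = []
    for lid in sorted(data.lists):
        stim = data.lists[lid]
        for it in stim.items:
            list_rows.append(
                (
                    lid,
                    it.serial_position,
                    it.word,
                    it.category,
                    int(it.is_buffer),
                    stim.modality,
                )
            )
    pd.DataFrame(list_rows, columns=list(LISTS_COLUMNS) + ["modality"]).to_csv(
        lists_path, index=False, lineterminator="\n"
    )


def write_lists(lists: Iterable[StimulusList], path: PathLike) -> None:
    """Write stimulus lists alone (the lists-CSV half of the schema)."""
    rows = []
    for stim in sorted(lists, key=lambda s: s.list_id):
        for it in stim.items:
            rows.append(
                (
                    stim.list_id,
                    it.serial_position,
                    it.word,
                    it.category,
                    int(it.is_buffer),
                    stim.modality,
                )
            )
    pd.DataFrame(rows, columns=list(LISTS_COLUMNS) + ["modality"]).to_csv(
        path, index=False, lineterminator="\n"
    )


def write_scored(data: StudyDataset, path: PathLike) -> None:
    """Events CSV augmented with classification and category columns."""
    rows = []
    for p in sorted(data.participants, key=lambda p: p.participant_id):
        for seq in sorted(p.sequences, key=lambda s: (s.timepoint, s.list_id)):
            for e in seq.events:
                rows.append(
                    (
                        p.participant_id,
                        p.group,
                        seq.timepoint,
                        seq.list_id,
                        e.output_position,
                        e.raw_word,
                        e.classification,
                        e.category or "",
                    )
                )
    pd.DataFrame(
        rows, columns=list(EVENTS_COLUMNS) + ["classification", "category"]
    ).to_csv(path, index=False, lineterminator="\n")


def write_estimates(
    estimates: Iterable[DynamicsEstimate], path: PathLike
) -> None:
    rows = [
        (e.metric, e.category, e.group, e.timepoint, e.numerator, e.denominator, e.value)
        for e in estimates
    ]
    pd.DataFrame(rows, columns=list(ESTIMATES_COLUMNS)).to_csv(
        path, index=False, lineterminator="\n"
    )


def write_results(results: Iterable[PermutationResult], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2, sort_keys=True)
        fh.write("\n")
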