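"""Pooled, valence-conditioned recall-dynamics statistics.

For each (group, timepoint) design cell the module computes, pooled over
all lists of all participants in the cell ("event-level" pooling — counts
are summed before division, never averaged per participant):

* ``pstart``  — probability the first retained recall of a list belongs to
  a category: lists starting with v / lists with a nonempty retained
  sequence.  Sums to 1 across categories.
* ``pstay``   — probability of staying within a category on the next
  retained transition: v->v transitions / transitions originating from v.
* ``pstop``   — per-recall stopping hazard: lists whose final retained
  recall is v / total retained recalls of v.  This reads stopping as "the
  probability that a given item is the last item recalled".
* ``terminal`` — alternative terminal-share reading of stopping: lists
  ending with v / lists with a nonempty retained sequence.  Sums to 1.
* ``recall_pct`` — percent of the studied category-v targets recalled.

Lists whose retained sequence is empty carry no information about the
dynamics and are dropped from pstart/pstay/pstop/terminal denominators,
but they still count in recall_pct denominators.  No outliers are removed
anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .data_model import CATEGORIES, DynamicsEstimate, StudyDataset
from .errors import UndefinedMetricError
from .recall_scoring import retained_category_sequence


@dataclass
class RetainedCounts:
    """Raw counts extracted from a collection of retained category sequences."""

    n_nonempty: int = 0
    starts: dict[str, int] = field(default_factory=dict)  # lists starting with v
    finals: dict[str, int] = field(default_factory=dict)  # lists ending with v
    stays: dict[str, int] = field(default_factory=dict)  # v->v transitions
    transitions_from: dict[str, int] = field(default_factory=dict)
    recalls: dict[str, int] = field(default_factory=dict)  # retained recalls of v

    def __post_init__(self) -> None:
        for c in CATEGORIES:
            self.starts.setdefault(c, 0)
            self.finals.setdefault(c, 0)
            self.stays.setdefault(c, 0)
            self.transitions_from.setdefault(c, 0)
            self.recalls.setdefault(c, 0)


def count_retained(category_sequences: Iterable[Sequence[str]]) -> RetainedCounts:
    """Tally starts, stays, transitions, recalls and terminals per category.

    Terminal recalls contribute no outgoing transition; a length-1 sequence
    contributes one start, one recall, one final, and no transitions.
    """
    rc = RetainedCounts()
    for cats in category_sequences:
        if not cats:
            continue
        rc.n_nonempty += 1
        rc.starts[cats[0]] += 1
        rc.finals[cats[-1]] += 1
        for c in cats:
            rc.recalls[c] += 1
        for a, b in zip(cats, cats[1:]):
            rc.transitions_from[a] += 1
            if a == b:
                rc.stays[a] += 1
    return rc


def _cell_retained(data: StudyDataset, group: str, timepoint: str) -> RetainedCounts:
    seqs = data.sequences_in_cell(group, timepoint)
    return count_retained(retained_category_sequence(s) for s in seqs)


def _require_nonempty(rc: RetainedCounts, group: str, timepoint: str) -> None:
    if rc.n_nonempty == 0:
        raise UndefinedMetricError(
            f"cell ({group}, {timepoint}) has no list with a nonempty retained "
            "sequence"
        )


def pooled_pstart(
    data: StudyDataset,
    group: str,
    timepoint: str,
    categories: Sequence[str] = CATEGORIES,
) -> dict[str, DynamicsEstimate]:
    """Probability of starting recall in each valence category."""
    rc = _cell_retained(data, group, timepoint)
    _require_nonempty(rc, group, timepoint)
    return {
        c: DynamicsEstimate.from_counts(
            "pstart", c, group, timepoint, rc.starts[c], rc.n_nonempty
        )
        for c in categories
    }


def pooled_pstay(
    data: StudyDataset,
    group: str,
    timepoint: str,
    categories: Sequence[str] = CATEGORIES,
) -> dict[str, DynamicsEstimate]:
    """Probability of staying in a category rather than switching out of it."""
    rc = _cell_retained(data, group, timepoint)
    out: dict[str, DynamicsEstimate] = {}
    for c in categories:
        if rc.transitions_from[c] == 0:
            raise UndefinedMetricError(
                f"pstay({c}) undefined in cell ({group}, {timepoint}): "
                "no retained transitions originate from this category"
            )
        out[c] = DynamicsEstimate.from_counts(
            "pstay", c, group, timepoint, rc.stays[c], rc.transitions_from[c]
        )
    return out


def pooled_pstop(
    data: StudyDataset,
    group: str,
    timepoint: str,
    categories: Sequence[str] = CATEGORIES,
) -> dict[str, DynamicsEstimate]:
    """Per-recall stopping hazard: probability a category-v recall is terminal."""
    rc = _cell_retained(data, group, timepoint)
    out: dict[str, DynamicsEstimate] = {}
    for c in categories:
        if rc.recalls[c] == 0:
            raise UndefinedMetricError(
                f"pstop({c}) undefined in cell ({group}, {timepoint}): "
                "no retained recalls of this category"
            )
        out[c] = DynamicsEstimate.from_counts(
            "pstop", c, group, timepoint, rc.finals[c], rc.recalls[c]
        )
    return out


def terminal_category_distribution(
    data: StudyDataset,
    group: str,
    timepoint: str,
    categories: Sequence[str] = CATEGORIES,
) -> dict[str, DynamicsEstimate]:
    """Share of lists whose recall ends in each category (sums to 1)."""
    rc = _cell_retained(data, group, timepoint)
    _require_nonempty(rc, group, timepoint)
    return {
        c: DynamicsEstimate.from_counts(
            "terminal", c, group, timepoint, rc.finals[c], rc.n_nonempty
        )
        for c in categories
    }


def recall_percentage(
    data: StudyDataset,
    group: str,
    timepoint: str,
    categories: Sequence[str] = CATEGORIES,
) -> dict[str, DynamicsEstimate]:
    """Percent of studied category-v targets recalled, pooled over lists.

    The numerator counts distinct recalled targets (target events are first
    occurrences by construction); the denominator is the number of studied
    category-v targets summed over all lists in the cell, including lists
    with no retained recalls.
    """
    seqs = data.sequences_in_cell(group, timepoint)
    if not seqs:
        raise UndefinedMetricError(f"cell ({group}, {timepoint}) contains no lists")
    num = {c: 0 for c in CATEGORIES}
    den = {c: 0 for c in CATEGORIES}
    for seq in seqs:
        stim = data.stimulus_for(seq)
        for c in CATEGORIES:
            den[c] += stim.target_count(c)
        for e in seq.events:
            if e.classification == "target":
                num[e.category] += 1  # type: ignore[index]
    out: dict[str, DynamicsEstimate] = {}
    for c in categories:
        if den[c] == 0:
            raise UndefinedMetricError(
                f"recall_pct({c}) undefined in cell ({group}, {timepoint}): "
                "no studied targets of this category"
            )
        out[c] = DynamicsEstimate.from_counts(
            "recall_pct", c, group, timepoint, num[c], den[c]
        )
    return out


_POOLED_FUNCS = {
    "pstart": pooled_pstart,
    "pstay": pooled_pstay,
    "pstop": pooled_pstop,
    "terminal": terminal_category_distribution,
    "recall_pct": recall_percentage,
}


def pooled_metric(
    data: StudyDataset,
    metric: str,
    group: str,
    timepoint: str,
    categories: Sequence[str] = CATEGORIES,
) -> dict[str, DynamicsEstimate]:
    """Dispatch to the pooled estimator named by ``metric``."""
    try:
        func = _POOLED_FUNCS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None
    return func(data, group, timepoint, categories)


def participant_mean_metric(
    data: StudyDataset,
    metric: str,
    category: str,
    group: str,
    timepoint: str,
) -> float:
    """Participant-weighted alternative: mean of per-participant proportions.

    Not the default pooling (the default sums counts over all participants
    before dividing); provided for sensitivity analyses.  Participants for
    whom the proportion is undefined are omitted.
    """
    values: list[float] = []
    for p in data.participants_in(group):
        sub = StudyDataset(participants=(p,), lists=data.lists)
        try:
            est = pooled_metric(sub, metric, group, timepoint, (category,))
        except UndefinedMetricError:
            continue
        values.append(est[category].value)
    if not values:
        raise UndefinedMetricError(
            f"{metric}({category}) undefined for every participant in "
            f"cell ({group}, {timepoint})"
        )
    return sum(values) / len(values)
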