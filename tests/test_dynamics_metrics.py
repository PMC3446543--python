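"""Pooled dynamics estimates: worked micro-examples and invariants."""

import numpy as np
import pytest

from recalldyn.data_model import CATEGORIES
from recalldyn.dynamics_metrics import (
    count_retained,
    participant_mean_metric,
    pooled_pstart,
    pooled_pstay,
    pooled_pstop,
    recall_percentage,
    terminal_category_distribution,
)
from recalldyn.errors import UndefinedMetricError
from recalldyn.recall_scoring import score_recall_sequence
from recalldyn.synthetic_data import composition_stimulus_list

from conftest import dataset_from_cells, random_participant_dataset


def test_pstart_direct_counts():
    firsts = ["negative", "positive", "negative", "neutral", "positive", "negative"]
    data = dataset_from_cells({("MBCT", "T1"): [[c] for c in firsts]})
    est = pooled_pstart(data, "MBCT", "T1")
    assert (est["positive"].numerator, est["positive"].denominator) == (2, 6)
    assert (est["negative"].numerator, est["negative"].denominator) == (3, 6)
    assert (est["neutral"].numerator, est["neutral"].denominator) == (1, 6)


def test_pstay_pstop_worked_micro_example():
    data = dataset_from_cells(
        {("control", "T2"): [["negative", "negative", "positive", "negative"]]}
    )
    stay = pooled_pstay(data, "control", "T2", ("negative", "positive"))
    assert (stay["negative"].numerator, stay["negative"].denominator) == (1, 2)
    assert (stay["positive"].numerator, stay["positive"].denominator) == (0, 1)
    stop = pooled_pstop(data, "control", "T2", ("negative", "positive"))
    assert (stop["negative"].numerator, stop["negative"].denominator) == (1, 3)
    assert (stop["positive"].numerator, stop["positive"].denominator) == (0, 1)


def test_single_category_runs_give_pstay_one():
    data = dataset_from_cells(
        {("MBCT", "T1"): [["positive"] * 4, ["negative"] * 3]}
    )
    est = pooled_pstay(data, "MBCT", "T1", ("positive", "negative"))
    assert est["positive"].value == 1.0
    assert est["negative"].value == 1.0


def test_single_recall_lists_give_pstop_one():
    data = dataset_from_cells({("MBCT", "T2"): [["positive"], ["negative"]]})
    est = pooled_pstop(data, "MBCT", "T2", ("positive", "negative"))
    assert est["positive"].value == est["negative"].value == 1.0


def test_terminal_distribution_direct_counts():
    ends = [["negative"], ["positive", "negative"], ["positive"], ["neutral"]]
    data = dataset_from_cells({("control", "T1"): ends})
    est = terminal_category_distribution(data, "control", "T1")
    assert est["positive"].value == pytest.approx(1 / 4)
    assert est["negative"].value == pytest.approx(2 / 4)
    assert est["neutral"].value == pytest.approx(1 / 4)


def test_pstart_and_terminal_sum_to_one_on_random_data():
    rng = np.random.default_rng(5)
    for _ in range(10):
        data = random_participant_dataset(rng, n_participants=5, n_lists=2)
        for g in ("MBCT", "control"):
            for t in ("T1", "T2"):
                try:
                    s = sum(e.value for e in pooled_pstart(data, g, t).values())
                    t_ = sum(
                        e.value
                        for e in terminal_category_distribution(data, g, t).values()
                    )
                except UndefinedMetricError:
                    continue
                assert s == pytest.approx(1.0, abs=1e-12)
                assert t_ == pytest.approx(1.0, abs=1e-12)


def test_stay_plus_switch_conserves_transitions():
    rng = np.random.default_rng(8)
    data = random_participant_dataset(rng, n_participants=6, n_lists=3)
    from recalldyn.recall_scoring import retained_category_sequence

    seqs = [
        retained_category_sequence(s)
        for p in data.participants
        for s in p.sequences
    ]
    rc = count_retained(seqs)
    # independent switch tally by direct pair scan
    switches = {c: 0 for c in CATEGORIES}
    for cats in seqs:
        for a, b in zip(cats, cats[1:]):
            if a != b:
                switches[a] += 1
    for c in CATEGORIES:
        assert rc.stays[c] + switches[c] == rc.transitions_from[c]


def test_recall_percentage_counts_and_order_invariance():
    stim = composition_stimulus_list(6, list_id="X")
    raw = ["neg0001", "neg0002", "pos0001"]
    rng = np.random.default_rng(0)
    values = set()
    for _ in range(10):
        shuffled = [raw[i] for i in rng.permutation(len(raw))]
        seq = score_recall_sequence(shuffled, stim, "p-MBCT", "T1")
        from recalldyn.data_model import ParticipantRecord, StudyDataset

        data = StudyDataset(
            (ParticipantRecord("p-MBCT", "MBCT", (seq,)),), {"X": stim}
        )
        est = recall_percentage(data, "MBCT", "T1")
        values.add(round(est["negative"].value, 9))
        assert est["negative"].value == pytest.approx(100 * 2 / 6)
    assert len(values) == 1  # invariant to recall order


def test_empty_retained_lists_drop_from_dynamics_but_not_recall_pct():
    stim = composition_stimulus_list(6, list_id="X")
    full = score_recall_sequence(["pos0001"], stim, "p-MBCT", "T1")
    empty = score_recall_sequence(["offlist"], stim, "p-MBCT", "T1")
    from recalldyn.data_model import ParticipantRecord, StudyDataset

    data = StudyDataset(
        (ParticipantRecord("p-MBCT", "MBCT", (full, empty)),), {"X": stim}
    )
    assert pooled_pstart(data, "MBCT", "T1")["positive"].denominator == 1
    assert recall_percentage(data, "MBCT", "T1")["positive"].denominator == 12


def test_undefined_cells_raise_named_errors():
    data = dataset_from_cells({("MBCT", "T1"): [["positive"]]})
    with pytest.raises(UndefinedMetricError, match="control"):
        pooled_pstart(data, "control", "T1")
    with pytest.raises(UndefinedMetricError, match="pstay"):
        pooled_pstay(data, "MBCT", "T1", ("negative",))
    with pytest.raises(UndefinedMetricError, match="pstop"):
        pooled_pstop(data, "MBCT", "T1", ("neutral",))


def test_event_level_pooling_differs_from_participant_mean():
    """Pooling sums counts before dividing; an unbalanced two-participant
    cell separates the two conventions."""
    stim = composition_stimulus_list(8, list_id="X")
    from conftest import sequence_from_categories
    from recalldyn.data_model import ParticipantRecord, StudyDataset

    heavy = sequence_from_categories(["negative"] * 5, stim, "a", "T1")
    light = sequence_from_categories(["negative", "positive"], stim, "b", "T1")
    data = StudyDataset(
        (
            ParticipantRecord("a", "MBCT", (heavy,)),
            ParticipantRecord("b", "MBCT", (light,)),
        ),
        {"X": stim},
    )
    pooled = pooled_pstay(data, "MBCT", "T1", ("negative",))["negative"].value
    per_participant = participant_mean_metric(data, "pstay", "negative", "MBCT", "T1")
    assert pooled == pytest.approx(4 / 5)  # (4 + 0) / (4 + 1)
    assert per_participant == pytest.approx((1.0 + 0.0) / 2)
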