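"""Permutation inference: label swaps, statistics, exactness, determinism."""

from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from recalldyn.data_model import ParticipantRecord, StudyDataset
from recalldyn.errors import (
    DegenerateDataError,
    UndefinedStatisticError,
)
from recalldyn.permutation_inference import (
    PermutationScheme,
    change_stat,
    exact_test,
    interaction_stat,
    permutation_test,
    permute_labels,
)
from recalldyn.dynamics_metrics import pooled_pstay
from recalldyn.synthetic_data import composition_stimulus_list

from conftest import (
    dataset_from_cells,
    random_participant_dataset,
    sequence_from_categories,
)


def test_scheme_requires_a_swap():
    with pytest.raises(ValueError):
        PermutationScheme()


def test_swap_group_conserves_label_multiset():
    rng = np.random.default_rng(0)
    data = random_participant_dataset(rng, n_participants=7, n_mbct=3)
    expected = Counter(p.group for p in data.participants)
    for _ in range(200):
        perm = permute_labels(data, PermutationScheme(swap_group=True), rng)
        assert Counter(p.group for p in perm.participants) == expected
        # recall content untouched
        assert [p.sequences for p in perm.participants] == [
            p.sequences for p in data.participants
        ]


def test_swap_time_single_participant_hits_both_datasets_evenly():
    rng = np.random.default_rng(1)
    data = random_participant_dataset(rng, n_participants=1, n_mbct=1)
    outcomes = Counter()
    for _ in range(1000):
        perm = permute_labels(data, PermutationScheme(swap_time=True), rng)
        tp_of_first = perm.participants[0].sequences[0].timepoint
        outcomes[tp_of_first] += 1
    assert set(outcomes) == {"T1", "T2"}
    # binomial(1000, 1/2): 500 +/- ~4.7 sd
    assert 420 <= outcomes["T1"] <= 580


def test_change_stat_zero_when_timepoints_identical():
    cells = {
        ("MBCT", "T1"): [["negative", "negative", "positive"]],
        ("MBCT", "T2"): [["negative", "negative", "positive"]],
        ("control", "T1"): [["negative", "positive"]],
        ("control", "T2"): [["negative", "positive"]],
    }
    data = dataset_from_cells(cells)
    assert change_stat(data, "pstay", "negative", "MBCT") == pytest.approx(0.0)
    assert interaction_stat(data, "pstay", "negative") == pytest.approx(0.0)


def test_change_stat_equals_direct_pooled_subtraction():
    rng = np.random.default_rng(4)
    for _ in range(5):
        data = random_participant_dataset(rng, n_participants=6, n_lists=3)
        for group in ("MBCT", "control"):
            try:
                direct = (
                    pooled_pstay(data, group, "T2", ("negative",))["negative"].value
                    - pooled_pstay(data, group, "T1", ("negative",))["negative"].value
                )
            except Exception:
                continue
            assert change_stat(data, "pstay", "negative", group) == pytest.approx(
                direct
            )


def test_interaction_is_antisymmetric_under_group_relabel():
    rng = np.random.default_rng(9)
    data = random_participant_dataset(rng, n_participants=6, n_mbct=3, n_lists=3)
    flipped = StudyDataset(
        tuple(
            ParticipantRecord(
                p.participant_id,
                "control" if p.group == "MBCT" else "MBCT",
                p.sequences,
            )
            for p in data.participants
        ),
        data.lists,
    )
    a = interaction_stat(data, "pstart", "negative")
    b = interaction_stat(flipped, "pstart", "negative")
    assert a == pytest.approx(-b)


def test_identical_data_everywhere_gives_p_one():
    seqs = [["negative", "positive", "negative"]] * 3
    cells = {(g, t): seqs for g in ("MBCT", "control") for t in ("T1", "T2")}
    data = dataset_from_cells(cells)
    res = permutation_test(data, "pstay", "negative", "interaction", seed=3)
    assert res.observed_stat == pytest.approx(0.0)
    assert res.p_value == 1.0
    exact = exact_test(data, "pstay", "negative", "time_within_group", group="MBCT")
    assert exact.p_value == 1.0


def test_permutation_test_is_deterministic():
    rng = np.random.default_rng(2)
    data = random_participant_dataset(rng, n_participants=8, n_lists=2)
    a = permutation_test(data, "pstart", "negative", "interaction", seed=11)
    b = permutation_test(data, "pstart", "negative", "interaction", seed=11)
    assert a == b
    c = permutation_test(data, "pstart", "negative", "interaction", seed=12)
    assert c.p_value != a.p_value or c.null_mean != a.null_mean


def test_fast_path_matches_relabeled_dataset_recomputation():
    """The counts-based replicate statistics equal change/interaction stats
    recomputed on an explicitly relabeled dataset."""
    rng = np.random.default_rng(6)
    data = random_participant_dataset(rng, n_participants=6, n_mbct=3, n_lists=3)
    from recalldyn.permutation_inference import (
        _participant_counts,
        _replicate_stats,
    )

    is_mbct, num, den = _participant_counts(data, "pstay", "negative")
    for trial in range(20):
        flips = rng.random(6) < 0.5
        order = rng.permutation(6)
        gmask = is_mbct[order]
        # build the equivalent relabeled dataset by hand
        swap = {"T1": "T2", "T2": "T1"}
        parts = []
        for i, p in enumerate(data.participants):
            seqs = p.sequences
            if flips[i]:
                seqs = tuple(replace(s, timepoint=swap[s.timepoint]) for s in seqs)
            group = "MBCT" if gmask[i] else "control"
            parts.append(ParticipantRecord(p.participant_id, group, seqs))
        relabeled = StudyDataset(tuple(parts), data.lists)
        stat, valid = _replicate_stats(
            num,
            den,
            gmask[None, :],
            flips[None, :],
            "interaction",
            None,
            1.0,
        )
        try:
            direct = interaction_stat(relabeled, "pstay", "negative")
        except UndefinedStatisticError:
            assert not valid[0]
            continue
        assert valid[0]
        assert stat[0] == pytest.approx(direct, abs=1e-12)


def test_exact_agrees_with_monte_carlo_on_small_fixture():
    """6-participant fixture: MC p within 3 Monte-Carlo SEs of the exact
    enumeration over all time flips."""
    rng = np.random.default_rng(13)
    data = random_participant_dataset(rng, n_participants=6, n_mbct=3, n_lists=2)
    exact = exact_test(data, "pstay", "negative", "time_within_group", group="MBCT")
    n_perm = 5000
    mc = permutation_test(
        data,
        "pstay",
        "negative",
        "time_within_group",
        group="MBCT",
        n_perm=n_perm,
        seed=21,
    )
    se = np.sqrt(exact.p_value * (1 - exact.p_value) / n_perm)
    assert abs(mc.p_value - exact.p_value) <= 3 * se + 2 / (n_perm + 1)


def test_decisions_stable_between_1000_and_5000_permutations():
    """On fixtures with p clearly away from 0.05 the alpha=0.05 decision
    does not depend on the iteration count."""
    rng = np.random.default_rng(17)
    null_data = random_participant_dataset(rng, n_participants=8, n_lists=3)
    strong = dataset_from_cells(
        {
            ("MBCT", "T1"): [["negative", "positive"] * 3] * 6,
            ("MBCT", "T2"): [["positive"] * 4 + ["negative", "negative"]] * 6,
            ("control", "T1"): [["negative", "positive"] * 3] * 6,
            ("control", "T2"): [["negative"] * 6] * 6,
        }
    )
    for data in (null_data, strong):
        p1 = permutation_test(
            data, "pstay", "negative", "interaction", n_perm=1000, seed=5
        ).p_value
        p5 = permutation_test(
            data, "pstay", "negative", "interaction", n_perm=5000, seed=5
        ).p_value
        if abs(p1 - 0.05) > 0.02:
            assert (p1 <= 0.05) == (p5 <= 0.05)


def test_p_value_invariant_to_consistent_category_relabel():
    rng = np.random.default_rng(23)
    data = random_participant_dataset(rng, n_participants=6, n_lists=3)
    swap = {"positive": "negative", "negative": "positive", "neutral": "neutral"}
    stim = composition_stimulus_list(6, list_id="X")
    parts = []
    for p in data.participants:
        seqs = []
        for s in p.sequences:
            from recalldyn.recall_scoring import retained_category_sequence

            cats = [swap[c] for c in retained_category_sequence(s)]
            seqs.append(
                sequence_from_categories(cats, stim, p.participant_id, s.timepoint)
            )
        parts.append(ParticipantRecord(p.participant_id, p.group, tuple(seqs)))
    relabeled = StudyDataset(tuple(parts), {"X": stim})
    a = permutation_test(data, "pstay", "negative", "interaction", seed=9)
    b = permutation_test(relabeled, "pstay", "positive", "interaction", seed=9)
    assert a.p_value == b.p_value
    assert a.observed_stat == pytest.approx(b.observed_stat)


def test_undefined_observed_statistic_raises():
    data = dataset_from_cells(
        {
            ("MBCT", "T1"): [["negative", "negative"]],
            ("MBCT", "T2"): [["negative"]],  # no transitions at T2
            ("control", "T1"): [["negative", "negative"]],
            ("control", "T2"): [["negative", "negative"]],
        }
    )
    with pytest.raises(UndefinedStatisticError):
        permutation_test(data, "pstay", "negative", "interaction", seed=0)


def test_mostly_empty_arms_trigger_degeneracy_error():
    stim = composition_stimulus_list(8, list_id="X")
    rich_a = sequence_from_categories(["negative"] * 3, stim, "a", "T1")
    rich_a2 = sequence_from_categories(["negative"] * 3, stim, "a", "T2")
    rich_b = sequence_from_categories(["negative", "negative"], stim, "b", "T1")
    rich_b2 = sequence_from_categories(["negative", "negative"], stim, "b", "T2")
    parts = [
        ParticipantRecord("a", "MBCT", (rich_a, rich_a2)),
        ParticipantRecord("b", "control", (rich_b, rich_b2)),
    ]
    for pid in ("c", "d", "e"):  # controls who never recall anything
        parts.append(
            ParticipantRecord(
                pid,
                "control",
                (
                    sequence_from_categories([], stim, pid, "T1"),
                    sequence_from_categories([], stim, pid, "T2"),
                ),
            )
        )
    data = StudyDataset(tuple(parts), {"X": stim})
    with pytest.raises(DegenerateDataError):
        permutation_test(data, "pstay", "negative", "interaction", seed=1)


def test_exact_enumeration_includes_identity_and_needs_no_smoothing():
    data = dataset_from_cells(
        {
            ("MBCT", "T1"): [["negative", "positive"]],
            ("MBCT", "T2"): [["negative", "negative"]],
            ("control", "T1"): [["negative", "positive"]],
            ("control", "T2"): [["negative", "positive"]],
        }
    )
    res = exact_test(data, "pstay", "negative", "time_within_group", group="MBCT")
    assert res.method == "exact"
    assert res.n_perm == 2  # one participant in the group -> 2 flips
    assert res.p_value in (0.5, 1.0)
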