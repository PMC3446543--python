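"""Generative model, trial simulator and block randomization."""

from collections import Counter

import numpy as np
import pytest

from recalldyn.data_model import CATEGORIES
from recalldyn.errors import CapacityError, ConfigurationError
from recalldyn.io import write_study
from recalldyn.recall_scoring import retained_category_sequence
from recalldyn.synthetic_data import (
    CategoryMarkovParams,
    baseline_params,
    block_randomize,
    composition_stimulus_list,
    effect_trial_design,
    expected_metrics_oracle,
    make_synthetic_norms,
    null_trial_design,
    shift_params,
    simulate_recall,
    simulate_trial,
)


def test_params_validation():
    with pytest.raises(ValueError):
        CategoryMarkovParams(start_probs=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        CategoryMarkovParams(stop_hazard=(1.0, 0.1, 0.1))
    with pytest.raises(ValueError):
        CategoryMarkovParams(stay_switch=((0.5, 0.5, 0.5),) * 3)


def test_shift_params_renormalizes_rows():
    base = baseline_params()
    shifted = shift_params(base, stay={"negative": -0.15, "positive": +0.15})
    mat = shifted.stay_array
    assert np.allclose(mat.sum(axis=1), 1.0)
    assert mat[1, 1] == pytest.approx(0.40)
    assert mat[0, 0] == pytest.approx(0.70)
    # off-diagonal masses keep their relative proportions
    assert mat[1, 0] == pytest.approx(mat[1, 2])
    with pytest.raises(ConfigurationError):
        shift_params(base, stop={"negative": +0.9})


def test_pure_positive_start():
    params = CategoryMarkovParams(
        start_probs=(1.0, 0.0, 0.0), stop_hazard=(0.5, 0.5, 0.5)
    )
    stim = composition_stimulus_list(6)
    rng = np.random.default_rng(0)
    for _ in range(200):
        seq = retained_category_sequence(simulate_recall(params, stim, rng))
        assert seq[0] == "positive"


def test_near_one_hazard_gives_length_one():
    params = CategoryMarkovParams(stop_hazard=(0.999, 0.999, 0.999))
    stim = composition_stimulus_list(6)
    rng = np.random.default_rng(1)
    lengths = [
        len(retained_category_sequence(simulate_recall(params, stim, rng)))
        for _ in range(2000)
    ]
    assert np.mean(np.array(lengths) == 1) >= 0.99


def test_no_word_repeats_within_sequence():
    params = baseline_params()
    stim = composition_stimulus_list(6)
    rng = np.random.default_rng(2)
    for _ in range(1000):
        seq = simulate_recall(params, stim, rng)
        words = [e.raw_word for e in seq.events]
        assert len(set(words)) == len(words)


def test_category_recalls_never_exceed_supply():
    params = CategoryMarkovParams(stop_hazard=(0.0, 0.0, 0.0), max_recalls=100)
    stim = composition_stimulus_list(6)
    rng = np.random.default_rng(3)
    for _ in range(200):
        cats = retained_category_sequence(simulate_recall(params, stim, rng))
        counts = Counter(cats)
        assert all(counts[c] <= 6 for c in CATEGORIES)
        assert len(cats) == 18  # zero hazard exhausts the list


def test_empty_list_raises_capacity_error():
    from recalldyn.data_model import StimulusList

    with pytest.raises(CapacityError):
        simulate_recall(
            baseline_params(), StimulusList("E", ()), np.random.default_rng(0)
        )


def test_injection_rates_produce_intrusions_and_repetitions():
    params = CategoryMarkovParams(
        stop_hazard=(0.1, 0.1, 0.1),
        intrusion_rate=0.3,
        repetition_rate=0.3,
        max_recalls=18,
    )
    stim = composition_stimulus_list(6)
    rng = np.random.default_rng(4)
    kinds = Counter()
    for _ in range(100):
        seq = simulate_recall(params, stim, rng)
        for e in seq.events:
            kinds[e.classification] += 1
        n_targets = sum(1 for e in seq.events if e.classification == "target")
        assert len(retained_category_sequence(seq)) == n_targets
    assert kinds["intrusion"] > 0 and kinds["repetition"] > 0


def test_default_trial_matches_study_design():
    data = simulate_trial(null_trial_design(seed=0))
    assert data.n_participants == 52
    groups = Counter(p.group for p in data.participants)
    assert groups == {"MBCT": 29, "control": 23}
    for p in data.participants:
        assert len(p.sequences_at("T1")) == 3
        assert len(p.sequences_at("T2")) == 3
    assert len(data.lists) == 6  # two counterbalanced sets of three


def test_trial_is_deterministic_and_seed_sensitive(tmp_path):
    d = dict(n_mbct=4, n_control=3, lists_per_assessment=2)
    a = simulate_trial(null_trial_design(seed=5, **d))
    b = simulate_trial(null_trial_design(seed=5, **d))
    write_study(a, tmp_path / "a_e.csv", tmp_path / "a_l.csv")
    write_study(b, tmp_path / "b_e.csv", tmp_path / "b_l.csv")
    assert (tmp_path / "a_e.csv").read_bytes() == (tmp_path / "b_e.csv").read_bytes()
    c = simulate_trial(null_trial_design(seed=6, **d))
    write_study(c, tmp_path / "c_e.csv", tmp_path / "c_l.csv")
    assert (tmp_path / "a_e.csv").read_bytes() != (tmp_path / "c_e.csv").read_bytes()


def test_zero_arm_size_rejected():
    with pytest.raises(ConfigurationError):
        null_trial_design(seed=0, n_mbct=0, n_control=5)


def test_block_randomize_ratios():
    rng = np.random.default_rng(0)
    assert Counter(block_randomize(5, rng=rng)) == {"MBCT": 3, "control": 2}
    assert Counter(block_randomize(10, rng=rng)) == {"MBCT": 6, "control": 4}
    with pytest.raises(ConfigurationError):
        block_randomize(10, block_size=5, ratio=(3, 3), rng=rng)


def test_block_randomize_partial_block_is_hypergeometric():
    """n=52: 10 complete blocks give 30 MBCT; the partial block of 2 adds
    0/1/2 MBCT with probabilities 1/10, 6/10, 3/10."""
    rng = np.random.default_rng(1)
    counts = Counter()
    n_draws = 4000
    for _ in range(n_draws):
        counts[Counter(block_randomize(52, rng=rng))["MBCT"]] += 1
    assert set(counts) <= {30, 31, 32}
    for k, p in ((30, 0.1), (31, 0.6), (32, 0.3)):
        se = np.sqrt(p * (1 - p) / n_draws)
        assert abs(counts[k] / n_draws - p) < 4 * se


def test_oracle_matches_parameters_without_depletion():
    params = CategoryMarkovParams(
        start_probs=(0.2, 0.5, 0.3),
        stay_switch=((0.7, 0.15, 0.15), (0.2, 0.6, 0.2), (0.25, 0.25, 0.5)),
        stop_hazard=(0.1, 0.3, 0.2),
        max_recalls=200,
    )
    from recalldyn.list_builder import ListSpec

    spec = ListSpec(n_per_category=500, n_buffers=4, total_length=1504)
    oracle = expected_metrics_oracle(params, spec, n_mc=20_000, seed=0)
    for i, c in enumerate(CATEGORIES):
        assert oracle["pstart"][c] == pytest.approx(params.start_probs[i], abs=0.01)
        assert oracle["pstay"][c] == pytest.approx(params.stay_switch[i][i], abs=0.01)
        assert oracle["pstop"][c] == pytest.approx(params.stop_hazard[i], abs=0.01)


def test_oracle_reflects_depletion_for_degenerate_params():
    """Start mass on positive, diagonal-1 stay, zero hazard: staying is
    forced until positives run out, so Pstay(positive) < 1 under depletion
    while the first six transitions are all stays."""
    params = CategoryMarkovParams(
        start_probs=(1.0, 0.0, 0.0),
        stay_switch=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)),
        stop_hazard=(0.0, 0.0, 0.0),
        max_recalls=100,
    )
    oracle = expected_metrics_oracle(params, n_mc=200, seed=1)
    assert oracle["pstart"]["positive"] == 1.0
    assert 0 < oracle["pstay"]["positive"] < 1  # depletion forces switches


def test_synthetic_norms_are_window_eligible():
    from recalldyn.list_builder import DEFAULT_WINDOWS

    norms = make_synthetic_norms(seed=0)
    by_prefix = {"pos": "positive", "neg": "negative", "neu": "neutral"}
    for n in norms:
        cat = by_prefix[n.word[:3]]
        assert DEFAULT_WINDOWS[cat].contains(n)
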