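"""Generative stand-in for the trial: a category-level Markov recall model.

No raw recall data are available for this design, so the package ships a
generative model under which the three dynamics statistics are sufficient
descriptions: recall is a Markov chain over valence categories with

* a start distribution over (positive, negative, neutral),
* a row-stochastic 3x3 stay/switch matrix (conditional on not stopping),
* a per-category stopping hazard, and
* sampling without replacement within categories (item depletion): when a
  category runs out of unrecalled targets, start and transition rows are
  renormalized over the categories that still have items.

This is a deliberate category-level approximation of retrieved-context
models (TCM/CMR), not a context-vector implementation; it is the minimal
process for which Pstart/Pstay/Pstop recovery is meaningful.  The module
also provides the trial simulator (two arms, two timepoints, per-cell
parameters, block randomization with blocks of 5 at a 3:2 ratio), a
synthetic norms generator for list construction, and a Monte-Carlo oracle
for the expected pooled metrics under depletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .data_model import (
    CATEGORIES,
    ListItem,
    ParticipantRecord,
    RecallSequence,
    StimulusList,
    StudyDataset,
    TIMEPOINTS,
    WordNorm,
)
from .errors import CapacityError, ConfigurationError
from .list_builder import ListSpec, build_stimulus_lists
from .recall_scoring import score_recall_sequence

_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class CategoryMarkovParams:
    """Parameters of the category-level Markov recall model.

    ``start_probs``, ``stay_switch`` rows and ``stop_hazard`` are ordered
    (positive, negative, neutral).  ``max_recalls`` caps sequence length.
    ``intrusion_rate``/``repetition_rate`` optionally inject non-target
    events into the transcript (default 0) to exercise scoring.
    """

    start_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    stay_switch: tuple[tuple[float, float, float], ...] = (
        (1 / 3, 1 / 3, 1 / 3),
    ) * 3
    stop_hazard: tuple[float, float, float] = (0.15, 0.15, 0.15)
    max_recalls: int = 30
    intrusion_rate: float = 0.0
    repetition_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_probs", tuple(self.start_probs))
        object.__setattr__(
            self, "stay_switch", tuple(tuple(r) for r in self.stay_switch)
        )
        object.__setattr__(self, "stop_hazard", tuple(self.stop_hazard))
        if len(self.start_probs) != 3 or abs(sum(self.start_probs) - 1) > 1e-9:
            raise ValueError("start_probs must be 3 probabilities summing to 1")
        if any(p < 0 for p in self.start_probs):
            raise ValueError("start_probs must be nonnegative")
        if len(self.stay_switch) != 3:
            raise ValueError("stay_switch must be 3x3")
        for row in self.stay_switch:
            if len(row) != 3 or abs(sum(row) - 1) > 1e-9 or any(p < 0 for p in row):
                raise ValueError("each stay_switch row must sum to 1")
        if len(self.stop_hazard) != 3 or not all(
            0 <= h < 1 for h in self.stop_hazard
        ):
            raise ValueError("stop hazards must lie in [0, 1)")
        if self.max_recalls < 1:
            raise ValueError("max_recalls must be positive")
        for r in (self.intrusion_rate, self.repetition_rate):
            if not 0 <= r < 1:
                raise ValueError("injection rates must lie in [0, 1)")

    @property
    def start_array(self) -> np.ndarray:
        return np.asarray(self.start_probs)

    @property
    def stay_array(self) -> np.ndarray:
        return np.asarray(self.stay_switch)

    @property
    def hazard_array(self) -> np.ndarray:
        return np.asarray(self.stop_hazard)


def baseline_params(max_recalls: int = 30) -> CategoryMarkovParams:
    """Baseline parameters emulating a stressed, partially remitted sample.

    Recall starts are negatively biased (start mass 0.50 on negative after
    a stressor that activates ruminative tendencies), within-valence
    clustering is well above chance (stay diagonal 0.55 vs. chance 1/3,
    the strong valence association networks the task probes), and stopping
    hazards are 0.08-0.15 with negative contexts stickiest, giving ~8
    retained recalls per 18-target list — overall recall in the mid-40%
    range, matching the levels this trial design produces.
    """
    return CategoryMarkovParams(
        start_probs=(0.25, 0.50, 0.25),
        stay_switch=(
            (0.55, 0.225, 0.225),
            (0.225, 0.55, 0.225),
            (0.225, 0.225, 0.55),
        ),
        stop_hazard=(0.08, 0.15, 0.08),
        max_recalls=max_recalls,
    )


def shift_params(
    params: CategoryMarkovParams,
    stay: Optional[dict[str, float]] = None,
    stop: Optional[dict[str, float]] = None,
    start: Optional[dict[str, float]] = None,
) -> CategoryMarkovParams:
    """Shift stay-diagonal / stop-hazard / start probabilities by category.

    Off-diagonal (and off-category) masses are renormalized proportionally
    so rows still sum to 1.  Shifts pushing any probability outside its
    valid range raise :class:`ConfigurationError`.
    """

    def _renorm(vec: np.ndarray, idx: int, delta: float) -> np.ndarray:
        new = vec.copy()
        target = vec[idx] + delta
        if not (0 <= target <= 1):
            raise ConfigurationError(
                f"shift {delta:+} pushes probability {vec[idx]} outside [0, 1]"
            )
        rest = 1 - vec[idx]
        new[idx] = target
        others = [i for i in range(3) if i != idx]
        if rest > 0:
            for i in others:
                new[i] = vec[i] * (1 - target) / rest
        else:
            for i in others:
                new[i] = (1 - target) / 2
        return new

    start_vec = params.start_array
    for c, d in (start or {}).items():
        start_vec = _renorm(start_vec, _CAT_INDEX[c], d)
    stay_mat = params.stay_array
    for c, d in (stay or {}).items():
        i = _CAT_INDEX[c]
        stay_mat = stay_mat.copy()
        stay_mat[i] = _renorm(stay_mat[i], i, d)
    hazard = params.hazard_array.copy()
    for c, d in (stop or {}).items():
        i = _CAT_INDEX[c]
        if not (0 <= hazard[i] + d < 1):
            raise ConfigurationError(
                f"stop shift {d:+} pushes hazard {hazard[i]} outside [0, 1)"
            )
        hazard[i] += d
    return CategoryMarkovParams(
        start_probs=tuple(start_vec),
        stay_switch=tuple(tuple(r) for r in stay_mat),
        stop_hazard=tuple(hazard),
        max_recalls=params.max_recalls,
        intrusion_rate=params.intrusion_rate,
        repetition_rate=params.repetition_rate,
    )


@dataclass
class TrialDesign:
    """A two-arm, two-timepoint trial: arm sizes, lists, per-cell params.

    Defaults mirror the target study design: 29 MBCT vs. 23 wait-list
    control participants, 3 lists per assessment, two counterbalanced list
    sets, T1/T2 assessments.
    """

    n_mbct: int = 29
    n_control: int = 23
    lists_per_assessment: int = 3
    list_spec: ListSpec = field(default_factory=ListSpec)
    cell_params: dict[tuple[str, str], CategoryMarkovParams] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mbct <= 0 or self.n_control <= 0:
            raise ConfigurationError("arm sizes must be positive")
        if self.lists_per_assessment < 1:
            raise ConfigurationError("lists_per_assessment must be >= 1")
        if not self.cell_params:
            base = baseline_params()
            self.cell_params = {
                (g, t): base for g in ("MBCT", "control") for t in TIMEPOINTS
            }
        for g in ("MBCT", "control"):
            for t in TIMEPOINTS:
                if (g, t) not in self.cell_params:
                    raise ConfigurationError(f"missing cell params for ({g}, {t})")

    @property
    def n_total(self) -> int:
        return self.n_mbct + self.n_control


def null_trial_design(
    seed: int = 0, params: Optional[CategoryMarkovParams] = None, **kwargs
) -> TrialDesign:
    """All four cells share the same generative parameters (no effect)."""
    base = params or baseline_params()
    cells = {(g, t): base for g in ("MBCT", "control") for t in TIMEPOINTS}
    return TrialDesign(cell_params=cells, seed=seed, **kwargs)


def effect_trial_design(
    effect: float = 0.15,
    seed: int = 0,
    params: Optional[CategoryMarkovParams] = None,
    **kwargs,
) -> TrialDesign:
    """Plant the study's qualitative T1->T2 pattern at magnitude ``effect``.

    MBCT at T2: negative stay down, positive stay up, negative stop hazard
    down; control at T2 drifts in the reverse directions.  T1 cells share
    the baseline.
    """
    base = params or baseline_params()
    mbct_t2 = shift_params(
        base,
        stay={"negative": -effect, "positive": +effect},
        stop={"negative": -effect},
    )
    ctrl_t2 = shift_params(
        base,
        stay={"negative": +effect, "positive": -effect},
        stop={"negative": +effect},
    )
    cells = {
        ("MBCT", "T1"): base,
        ("control", "T1"): base,
        ("MBCT", "T2"): mbct_t2,
        ("control", "T2"): ctrl_t2,
    }
    return TrialDesign(cell_params=cells, seed=seed, **kwargs)


def _draw(rng: np.random.Generator, probs: np.ndarray) -> int:
    return int(np.searchsorted(np.cumsum(probs), rng.random(), side="right"))


def simulate_recall(
    params: CategoryMarkovParams,
    stim: StimulusList,
    rng: np.random.Generator,
    participant_id: str = "sim",
    timepoint: str = "T1",
    list_id: Optional[str] = None,
) -> RecallSequence:
    """Draw one recall sequence from the category-Markov model.

    The first category comes from ``start_probs`` restricted to categories
    with unrecalled targets (renormalized); items are drawn uniformly
    without replacement within a category; after each recall from category
    c the chain stops with probability ``stop_hazard[c]``, otherwise the
    next category is drawn from the c-th stay/switch row adjusted for item
    depletion.  The depletion rule preserves the stay tendency: staying in
    the current train is a property of the current context, so while the
    current category still holds unrecalled items its stay probability is
    kept as parameterized and only the mass of exhausted *switch*
    categories is redistributed (proportionally) among the remaining
    switch categories; when every switch target is exhausted the chain
    stays, and when the current category itself is exhausted the row is
    renormalized over whatever remains.  Recall ends when every target is
    exhausted or ``max_recalls`` target recalls have been made.  Only
    target words are emitted unless injection rates are positive.
    """
    remaining: list[list[str]] = [
        [it.word for it in stim.targets if it.category == c] for c in CATEGORIES
    ]
    if not any(remaining):
        raise CapacityError(f"list {stim.list_id!r} has no target words")

    raw: list[str] = []
    avail = np.array([len(r) > 0 for r in remaining])
    probs = params.start_array * avail
    total = probs.sum()
    if total <= 0:
        # start mass entirely on exhausted categories: fall back to uniform
        probs = avail.astype(float)
        total = probs.sum()
    cat = _draw(rng, probs / total)
    n_recalled = 0
    while True:
        bucket = remaining[cat]
        word = bucket.pop(int(rng.integers(len(bucket))))
        raw.append(word)
        n_recalled += 1
        if params.repetition_rate and len(raw) > 1:
            if rng.random() < params.repetition_rate:
                raw.append(raw[int(rng.integers(len(raw) - 1))])
        if params.intrusion_rate and rng.random() < params.intrusion_rate:
            raw.append(f"xintr{n_recalled}")
        avail = np.array([len(r) > 0 for r in remaining])
        if n_recalled >= params.max_recalls or not avail.any():
            break
        if rng.random() < params.stop_hazard[cat]:
            break
        row = params.stay_array[cat]
        if avail[cat]:
            # stay mass is preserved; exhausted switch mass redistributes
            # proportionally among the remaining switch categories
            switch = row.copy()
            switch[cat] = 0.0
            switch_avail = switch * avail
            probs = np.zeros(3)
            probs[cat] = row[cat]
            if switch_avail.sum() > 0:
                probs += switch_avail * (switch.sum() / switch_avail.sum())
            else:
                probs[cat] = 1.0
        else:
            probs = row * avail
            if probs.sum() <= 0:
                probs = avail.astype(float)
        cat = _draw(rng, probs / probs.sum())
    return score_recall_sequence(raw, stim, participant_id, timepoint, list_id)


def make_synthetic_norms(
    n_positive: int = 48,
    n_negative: int = 48,
    n_neutral: int = 80,
    seed: int = 0,
) -> list[WordNorm]:
    """Synthetic ANEW-style norms table for tests and simulations.

    Words are synthetic tokens (``pos001`` ...), with valence/arousal drawn
    from per-category normal distributions matching the nominal category
    means/SDs, truncated to the default selection windows, and length and
    frequency drawn identically across categories so that lists are
    balanceable.  Real norms tables are user input; nothing proprietary is
    bundled.
    """
    rng = np.random.default_rng(seed)
    specs = {
        "positive": (n_positive, 7.5, 0.40, 5.8, 0.80),
        "negative": (n_negative, 2.6, 0.73, 5.5, 1.37),
        "neutral": (n_neutral, 5.18, 0.34, 3.84, 0.48),
    }
    from .list_builder import DEFAULT_WINDOWS

    out: list[WordNorm] = []
    for cat, (n, vm, vs, am, asd) in specs.items():
        win = DEFAULT_WINDOWS[cat]
        for i in range(n):
            val = _truncated_normal(rng, vm, vs, *win.valence)
            aro = _truncated_normal(rng, am, asd, *win.arousal)
            freq = float(rng.lognormal(mean=2.5, sigma=1.0))
            length = int(np.clip(round(rng.normal(6.0, 1.8)), 3, 12))
            out.append(
                WordNorm(f"{cat[:3]}{i + 1:03d}", val, aro, freq, length)
            )
    return out


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def block_randomize(
    n_total: int,
    block_size: int = 5,
    ratio: tuple[int, int] = (3, 2),
    rng: Optional[np.random.Generator] = None,
) -> list[str]:
    """Block randomization to (MBCT, control) at ``ratio`` within blocks.

    Each complete block contains exactly ratio[0] MBCT and ratio[1] control
    labels in uniform random order; a final partial block is a uniform draw
    without replacement from a fresh block's labels.
    """
    if sum(ratio) != block_size:
        raise ConfigurationError(
            f"ratio {ratio} must sum to block_size {block_size}"
        )
    if rng is None:
        rng = np.random.default_rng()
    labels = ["MBCT"] * ratio[0] + ["control"] * ratio[1]
    out: list[str] = []
    while len(out) < n_total:
        block = [labels[i] for i in rng.permutation(block_size)]
        out.extend(block[: n_total - len(out)])
    return out


def simulate_trial(design: TrialDesign) -> StudyDataset:
    """Simulate the full trial: lists, arm assignment, all recall sequences.

    Fully deterministic given ``design.seed``: norms, list construction,
    group assignment and every participant's recalls run on seed-derived
    substreams, so identical designs produce byte-identical event tables.
    The two list sets are counterbalanced across participants (alternating
    which set is seen at T1).
    """
    ss = np.random.SeedSequence(design.seed)
    ss_norms, ss_lists, ss_assign, ss_recall = ss.spawn(4)

    spec = design.list_spec
    n_lists_total = spec.n_list_sets * design.lists_per_assessment
    per_cat = n_lists_total * spec.n_per_category
    n_neutral = per_cat + n_lists_total * spec.n_buffers
    norms = make_synthetic_norms(
        n_positive=max(48, per_cat + 8),
        n_negative=max(48, per_cat + 8),
        n_neutral=max(80, n_neutral + 8),
        seed=int(ss_norms.generate_state(1)[0] % 2**31),
    )
    lists = build_stimulus_lists(
        norms,
        spec,
        n_lists=n_lists_total,
        seed=int(ss_lists.generate_state(1)[0] % 2**31),
    )
    sets = [
        lists[i * design.lists_per_assessment : (i + 1) * design.lists_per_assessment]
        for i in range(spec.n_list_sets)
    ]

    rng_assign = np.random.default_rng(ss_assign)
    groups = ["MBCT"] * design.n_mbct + ["control"] * design.n_control
    groups = [groups[i] for i in rng_assign.permutation(len(groups))]

    part_seeds = ss_recall.spawn(design.n_total)
    participants: list[ParticipantRecord] = []
    for i in range(design.n_total):
        pid = f"P{i + 1:03d}"
        group = groups[i]
        rng = np.random.default_rng(part_seeds[i])
        seqs: list[RecallSequence] = []
        for j, tp in enumerate(TIMEPOINTS):
            set_idx = (i + j) % len(sets)  # counterbalanced set order
            params = design.cell_params[(group, tp)]
            for stim in sets[set_idx]:
                seqs.append(
                    simulate_recall(params, stim, rng, pid, tp, stim.list_id)
                )
        participants.append(ParticipantRecord(pid, group, tuple(seqs)))
    return StudyDataset(
        tuple(participants), {s.list_id: s for s in lists}
    )


def composition_stimulus_list(
    n_per_category: int, list_id: str = "MC"
) -> StimulusList:
    """A bare composition-only list (no buffers) for simulation studies,
    e.g. depletion-free runs with hundreds of items per category."""
    items: list[ListItem] = []
    pos = 1
    for c in CATEGORIES:
        for i in range(n_per_category):
            items.append(ListItem(f"{c[:3]}{i + 1:04d}", pos, c))
            pos += 1
    return StimulusList(list_id, tuple(items))


def expected_metrics_oracle(
    params: CategoryMarkovParams,
    list_spec: Optional[ListSpec] = None,
    n_mc: int = 10_000,
    seed: int = 0,
) -> dict[str, dict[str, Optional[float]]]:
    """Monte-Carlo expectation of pooled Pstart/Pstay/Pstop under depletion.

    Simulates ``n_mc`` fresh sequences on a list with the spec's per
    category composition and pools the three statistics; the reference
    value for parameter-recovery checks.  A category with no observations
    maps to None.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    spec = list_spec or ListSpec()
    stim = composition_stimulus_list(spec.n_per_category)
    rng = np.random.default_rng(seed)
    from .dynamics_metrics import count_retained
    from .recall_scoring import retained_category_sequence

    seqs = (
        retained_category_sequence(simulate_recall(params, stim, rng))
        for _ in range(n_mc)
    )
    rc = count_retained(seqs)
    out: dict[str, dict[str, Optional[float]]] = {
        "pstart": {},
        "pstay": {},
        "pstop": {},
    }
    for c in CATEGORIES:
        out["pstart"][c] = (
            rc.starts[c] / rc.n_nonempty if rc.n_nonempty else None
        )
        out["pstay"][c] = (
            rc.stays[c] / rc.transitions_from[c]
            if rc.transitions_from[c]
            else None
        )
        out["pstop"][c] = rc.finals[c] / rc.recalls[c] if rc.recalls[c] else None
    return out
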