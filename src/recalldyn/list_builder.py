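"""Construction and validation of affective stimulus lists.

The default design is the 22-word list: 6 positive, 6 negative and 6
neutral target words framed by 4 neutral buffer words (2 at each edge,
controlling primacy and recency; buffers are excluded from analysis).
Target words are ordered with no two consecutive words sharing a valence
category; per-category valence/arousal means must sit near nominal targets
(positive 7.5/5.8, negative 2.6/5.5, neutral 5.18/3.84 on the 1-9 scale),
and lists within a set are balanced against each other on mean valence,
arousal, word length and log frequency.  Two disjoint list sets support
counterbalanced pre/post administration.

Construction is stratified sampling per category followed by a seeded
hill-climb of same-category swaps to repair mean and balance violations,
then shuffle-until-valid ordering with a bounded retry count; everything is
deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .data_model import (
    CATEGORIES,
    ListItem,
    StimulusList,
    WordNorm,
    norms_by_word,
)
from .errors import (
    CapacityError,
    ConstraintFailureError,
    NormsLookupError,
)


@dataclass(frozen=True)
class CategoryWindow:
    """Inclusive (lo, hi) selection windows on the valence and arousal axes."""

    valence: tuple[float, float]
    arousal: tuple[float, float]

    def contains(self, norm: WordNorm) -> bool:
        return (
            self.valence[0] <= norm.valence <= self.valence[1]
            and self.arousal[0] <= norm.arousal <= self.arousal[1]
        )


# Windows are roughly nominal mean +/- 2 SD; the neutral valence band is
# disjoint from both affective bands so category membership is unambiguous.
DEFAULT_WINDOWS: dict[str, CategoryWindow] = {
    "positive": CategoryWindow(valence=(6.7, 9.0), arousal=(4.2, 7.4)),
    "negative": CategoryWindow(valence=(1.0, 4.1), arousal=(2.8, 8.2)),
    "neutral": CategoryWindow(valence=(4.5, 5.9), arousal=(2.9, 4.8)),
}

#: nominal per-category (valence, arousal) means the composed lists aim for
DEFAULT_TARGET_MEANS: dict[str, tuple[float, float]] = {
    "positive": (7.5, 5.8),
    "negative": (2.6, 5.5),
    "neutral": (5.18, 3.84),
}

DEFAULT_BALANCE_TOLERANCE: dict[str, float] = {
    "valence": 0.5,
    "arousal": 0.6,
    "length": 1.5,
    "log_frequency": 0.8,
}


@dataclass
class ListSpec:
    """Composition, window, mean and balance constraints for one list design."""

    n_per_category: int = 6
    n_buffers: int = 4
    total_length: int = 22
    category_windows: dict[str, CategoryWindow] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    target_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_MEANS)
    )
    mean_tolerance: float = 0.5
    balance_tolerance: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BALANCE_TOLERANCE)
    )
    n_list_sets: int = 2
    buffer_split: tuple[int, int] = (2, 2)
    #: the no-consecutive-same-valence constraint applies to target words
    #: only; neutral buffers at the edges are exempt
    ordering_over_targets_only: bool = True

    def __post_init__(self) -> None:
        if self.total_length != 3 * self.n_per_category + self.n_buffers:
            raise ValueError(
                "total_length must equal 3 * n_per_category + n_buffers "
                f"({self.total_length} != {3 * self.n_per_category + self.n_buffers})"
            )
        if sum(self.buffer_split) != self.n_buffers:
            raise ValueError("buffer_split must sum to n_buffers")
        for c in CATEGORIES:
            if c not in self.category_windows:
                raise ValueError(f"missing category window for {c!r}")
        pairs = [
            ("positive", "neutral"),
            ("negative", "neutral"),
            ("positive", "negative"),
        ]
        for a, b in pairs:
            wa, wb = self.category_windows[a].valence, self.category_windows[b].valence
            if max(wa[0], wb[0]) <= min(wa[1], wb[1]):
                raise ValueError(
                    f"valence windows of {a!r} and {b!r} overlap; category "
                    "membership would be ambiguous"
                )


@dataclass(frozen=True)
class CheckResult:
    passed: bool
    message: str = ""


@dataclass
class ValidationReport:
    """Per-constraint pass/fail entries; never raises on a failed check."""

    checks: dict[str, CheckResult] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks.values())

    def failures(self) -> dict[str, CheckResult]:
        return {k: v for k, v in self.checks.items() if not v.passed}


def eligible_words(
    norms: Iterable[WordNorm], spec: ListSpec
) -> dict[str, list[WordNorm]]:
    """Words falling inside each category's valence/arousal window."""
    table = norms_by_word(norms)
    out: dict[str, list[WordNorm]] = {c: [] for c in CATEGORIES}
    for norm in table.values():
        for c in CATEGORIES:
            if spec.category_windows[c].contains(norm):
                out[c].append(norm)
                break  # valence windows are disjoint
    return out


def has_consecutive_repeat(categories: Sequence[str]) -> bool:
    """True if any two consecutive entries share a category."""
    return any(a == b for a, b in zip(categories, categories[1:]))


def _feature_means(words: Sequence[WordNorm]) -> dict[str, float]:
    return {
        "valence": float(np.mean([w.valence for w in words])),
        "arousal": float(np.mean([w.arousal for w in words])),
        "length": float(np.mean([w.length for w in words])),
        "log_frequency": float(np.mean([math.log1p(w.frequency) for w in words])),
    }


def _assignment_cost(
    lists_words: list[dict[str, list[WordNorm]]], spec: ListSpec
) -> float:
    """Total excess over tolerance for per-list category means and
    pairwise between-list balance; 0 when all constraints hold."""
    cost = 0.0
    for words_by_cat in lists_words:
        for c in CATEGORIES:
            tv, ta = spec.target_means[c]
            mv = float(np.mean([w.valence for w in words_by_cat[c]]))
            ma = float(np.mean([w.arousal for w in words_by_cat[c]]))
            cost += max(0.0, abs(mv - tv) - spec.mean_tolerance)
            cost += max(0.0, abs(ma - ta) - spec.mean_tolerance)
    means = [
        _feature_means([w for c in CATEGORIES for w in lw[c]]) for lw in lists_words
    ]
    for i in range(len(means)):
        for j in range(i + 1, len(means)):
            for feat, tol in spec.balance_tolerance.items():
                cost += max(0.0, abs(means[i][feat] - means[j][feat]) - tol)
    return cost


def _order_targets(
    words_by_cat: dict[str, list[WordNorm]],
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> list[tuple[str, str]]:
    """Shuffle (word, category) pairs until no two consecutive categories
    repeat; bounded retries."""
    pairs = [(w.word, c) for c in CATEGORIES for w in words_by_cat[c]]
    for _ in range(max_tries):
        perm = rng.permutation(len(pairs))
        ordered = [pairs[i] for i in perm]
        if not has_consecutive_repeat([c for _, c in ordered]):
            return ordered
    raise ConstraintFailureError(
        f"no valid target ordering found in {max_tries} shuffles"
    )


def build_stimulus_lists(
    norms: Iterable[WordNorm],
    spec: Optional[ListSpec] = None,
    n_lists: int = 3,
    seed: int = 0,
    id_prefix: str = "L",
    max_repair: int = 4000,
) -> list[StimulusList]:
    """Build ``n_lists`` mutually word-disjoint lists satisfying ``spec``.

    Deterministic given (norms, spec, n_lists, seed).  Raises
    :class:`CapacityError` when a category lacks eligible words and
    :class:`ConstraintFailureError` when the mean/balance/ordering
    constraints cannot be met within bounded retries.
    """
    spec = spec or ListSpec()
    norms = list(norms)
    rng = np.random.default_rng(seed)
    eligible = eligible_words(norms, spec)

    need = {c: n_lists * spec.n_per_category for c in CATEGORIES}
    need["neutral"] += n_lists * spec.n_buffers
    for c in CATEGORIES:
        if len(eligible[c]) < need[c]:
            raise CapacityError(
                f"category {c!r}: {len(eligible[c])} eligible words, "
                f"{need[c]} needed for {n_lists} lists"
            )

    # stratified initial assignment + leftover pools
    pools: dict[str, list[WordNorm]] = {}
    lists_words: list[dict[str, list[WordNorm]]] = [
        {c: [] for c in CATEGORIES} for _ in range(n_lists)
    ]
    for c in CATEGORIES:
        shuffled = [eligible[c][i] for i in rng.permutation(len(eligible[c]))]
        for li in range(n_lists):
            take = shuffled[
                li * spec.n_per_category : (li + 1) * spec.n_per_category
            ]
            lists_words[li][c] = take
        pools[c] = shuffled[n_lists * spec.n_per_category :]

    # buffers come off the top of the remaining neutral pool
    buffer_words: list[list[WordNorm]] = []
    for li in range(n_lists):
        buffer_words.append(pools["neutral"][: spec.n_buffers])
        pools["neutral"] = pools["neutral"][spec.n_buffers :]

    # hill-climb repair: same-category swaps within/between lists and pool
    cost = _assignment_cost(lists_words, spec)
    for _ in range(max_repair):
        if cost <= 0.0:
            break
        c = CATEGORIES[int(rng.integers(3))]
        li = int(rng.integers(n_lists))
        wi = int(rng.integers(spec.n_per_category))
        # swap partner: another list's slot or the leftover pool
        use_pool = pools[c] and (n_lists == 1 or rng.random() < 0.5)
        if use_pool:
            pi = int(rng.integers(len(pools[c])))
            lists_words[li][c][wi], pools[c][pi] = (
                pools[c][pi],
                lists_words[li][c][wi],
            )
            undo = ("pool", c, li, wi, pi)
        else:
            lj = int(rng.integers(n_lists))
            if lj == li:
                continue
            wj = int(rng.integers(spec.n_per_category))
            lists_words[li][c][wi], lists_words[lj][c][wj] = (
                lists_words[lj][c][wj],
                lists_words[li][c][wi],
            )
            undo = ("list", c, li, wi, lj, wj)
        new_cost = _assignment_cost(lists_words, spec)
        if new_cost < cost:
            cost = new_cost
        elif undo[0] == "pool":
            _, c, li, wi, pi = undo
            lists_words[li][c][wi], pools[c][pi] = (
                pools[c][pi],
                lists_words[li][c][wi],
            )
        else:
            _, c, li, wi, lj, wj = undo
            lists_words[li][c][wi], lists_words[lj][c][wj] = (
                lists_words[lj][c][wj],
                lists_words[li][c][wi],
            )
    if cost > 0.0:
        raise ConstraintFailureError(
            f"mean/balance constraints unsatisfied after {max_repair} repair "
            f"steps (residual violation {cost:.3f}); widen tolerances or "
            "supply more candidate words"
        )

    out: list[StimulusList] = []
    for li in range(n_lists):
        ordered = _order_targets(lists_words[li], rng)
        head, tail = spec.buffer_split
        items: list[ListItem] = []
        pos = 1
        for bw in buffer_words[li][:head]:
            items.append(ListItem(bw.word, pos, "neutral", is_buffer=True))
            pos += 1
        for word, cat in ordered:
            items.append(ListItem(word, pos, cat))
            pos += 1
        for bw in buffer_words[li][head:]:
            items.append(ListItem(bw.word, pos, "neutral", is_buffer=True))
            pos += 1
        # mirror the two-visual-one-aural presentation pattern
        modality = "aural" if li % 3 == 1 else "visual"
        out.append(StimulusList(f"{id_prefix}{li + 1}", tuple(items), modality))
    return out


def validate_stimulus_list(
    stim: StimulusList,
    spec: Optional[ListSpec] = None,
    norms: Optional[Iterable[WordNorm]] = None,
) -> ValidationReport:
    """Per-list constraint report: composition, buffer placement, ordering,
    uniqueness, and (when norms are given) per-category means.

    A failed constraint yields a failed check, never an exception; only a
    stimulus word missing from a supplied norms table raises
    :class:`NormsLookupError`.
    """
    spec = spec or ListSpec()
    report = ValidationReport()
    targets = stim.targets
    counts = {c: stim.target_count(c) for c in CATEGORIES}
    report.checks["composition"] = CheckResult(
        len(stim.items) == spec.total_length
        and all(counts[c] == spec.n_per_category for c in CATEGORIES)
        and len(stim.buffers) == spec.n_buffers,
        f"{len(stim.items)} items, targets {counts}, {len(stim.buffers)} buffers",
    )
    head, tail = spec.buffer_split
    n = len(stim.items)
    edge_ok = all(
        it.is_buffer == (it.serial_position <= head or it.serial_position > n - tail)
        for it in stim.items
    ) and all(it.category == "neutral" for it in stim.buffers)
    report.checks["buffer_placement"] = CheckResult(
        edge_ok, f"expected {head} leading and {tail} trailing neutral buffers"
    )
    seq = (
        [it.category for it in targets]
        if spec.ordering_over_targets_only
        else [it.category for it in stim.items]
    )
    report.checks["ordering"] = CheckResult(
        not has_consecutive_repeat(seq),
        "no two consecutive same-category words",
    )
    words = [it.word for it in stim.items]
    report.checks["uniqueness"] = CheckResult(
        len(set(words)) == len(words), "no word appears twice"
    )
    if norms is not None:
        table = norms_by_word(norms)
        for c in CATEGORIES:
            cat_words = [it.word for it in targets if it.category == c]
            missing = [w for w in cat_words if w not in table]
            if missing:
                raise NormsLookupError(
                    f"words {missing} absent from norms table during mean check"
                )
            if not cat_words:
                report.checks[f"means_{c}"] = CheckResult(False, "no targets")
                continue
            tv, ta = spec.target_means[c]
            mv = float(np.mean([table[w].valence for w in cat_words]))
            ma = float(np.mean([table[w].arousal for w in cat_words]))
            ok = (
                abs(mv - tv) <= spec.mean_tolerance
                and abs(ma - ta) <= spec.mean_tolerance
            )
            report.checks[f"means_{c}"] = CheckResult(
                ok,
                f"valence {mv:.2f} (target {tv}), arousal {ma:.2f} (target {ta})",
            )
    return report


def validate_list_set(
    lists: Sequence[StimulusList],
    spec: Optional[ListSpec] = None,
    norms: Optional[Iterable[WordNorm]] = None,
) -> ValidationReport:
    """Cross-list constraints: word disjointness and pairwise balance."""
    spec = spec or ListSpec()
    report = ValidationReport()
    all_words = [it.word for stim in lists for it in stim.items]
    report.checks["word_disjointness"] = CheckResult(
        len(set(all_words)) == len(all_words), "no word reused across lists"
    )
    if norms is not None and len(lists) > 1:
        table = norms_by_word(norms)
        means = []
        for stim in lists:
            tw = [it.word for it in stim.targets]
            missing = [w for w in tw if w not in table]
            if missing:
                raise NormsLookupError(
                    f"words {missing} absent from norms table during balance check"
                )
            means.append(_feature_means([table[w] for w in tw]))
        for feat, tol in spec.balance_tolerance.items():
            diffs = [
                abs(means[i][feat] - means[j][feat])
                for i in range(len(means))
                for j in range(i + 1, len(means))
            ]
            report.checks[f"balance_{feat}"] = CheckResult(
                max(diffs) <= tol,
                f"max pairwise difference {max(diffs):.3f} (tolerance {tol})",
            )
    return report
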