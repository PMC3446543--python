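"""Permutation analogs of ANOVA for pooled recall-dynamics estimates.

Inference relabels the design factors and recomputes the pooled statistic:

* within-group change (``time_within_group``): statistic is
  M(group, T2) - M(group, T1); the null is built by exchanging each
  participant's T1/T2 labels independently with probability 1/2, all of a
  participant's lists moving together.
* group x time ``interaction``: statistic is the difference of differences
  [M(MBCT, T2) - M(MBCT, T1)] - [M(control, T2) - M(control, T1)]; the null
  additionally permutes group labels across participants (arm sizes
  preserved), applying both swaps jointly.

Participants are the exchange units: group labels permute *between*
participants and time labels flip *within* participants, which respects the
dependence among one participant's lists.  p-values use add-one smoothing,
p = (1 + #{|perm| >= |obs|}) / (1 + n_perm), so Monte-Carlo p-values are
never zero; :func:`exact_test` enumerates the complete relabeling space
(identity included) for small datasets and needs no smoothing.

Because relabeling never alters recall content, each participant's
per-timepoint count contributions to the pooled statistic are precomputed
once and every replicate is recomputed from those counts; this is exactly
equivalent to rescoring the relabeled dataset (a property covered by the
test suite via :func:`permute_labels`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from math import comb
from typing import Optional

import numpy as np

from .data_model import (
    CATEGORIES,
    GROUPS,
    METRICS,
    ParticipantRecord,
    PermutationResult,
    StudyDataset,
    TIMEPOINTS,
)
from .dynamics_metrics import count_retained
from .errors import (
    CapacityError,
    DegenerateDataError,
    UndefinedStatisticError,
)
from .recall_scoring import retained_category_sequence

_TIE_TOL = 1e-9  # float slack when comparing permuted and observed statistics


@dataclass(frozen=True)
class PermutationScheme:
    """Which design labels are exchanged when building the null."""

    swap_group: bool = False
    swap_time: bool = False

    def __post_init__(self) -> None:
        if not (self.swap_group or self.swap_time):
            raise ValueError("at least one of swap_group/swap_time must be set")


def permute_labels(
    data: StudyDataset, scheme: PermutationScheme, rng: np.random.Generator
) -> StudyDataset:
    """Return a dataset with relabeled design factors and untouched recalls.

    With ``swap_group`` the multiset of group labels is randomly reassigned
    across participants (arm sizes preserved); with ``swap_time`` each
    participant's T1/T2 labels are independently exchanged with probability
    1/2, every list of an assessment moving together.
    """
    parts = data.participants
    n = len(parts)
    if scheme.swap_group:
        labels = [parts[i].group for i in rng.permutation(n)]
    else:
        labels = [p.group for p in parts]
    flips = rng.random(n) < 0.5 if scheme.swap_time else np.zeros(n, dtype=bool)
    swap = {"T1": "T2", "T2": "T1"}
    new_parts = []
    for p, group, flip in zip(parts, labels, flips):
        seqs = p.sequences
        if flip:
            seqs = tuple(replace(s, timepoint=swap[s.timepoint]) for s in seqs)
        new_parts.append(ParticipantRecord(p.participant_id, group, seqs))
    return StudyDataset(tuple(new_parts), data.lists)


def _participant_counts(
    data: StudyDataset, metric: str, category: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-participant, per-timepoint (numerator, denominator) contributions.

    Returns (is_mbct (n,), num (n, 2), den (n, 2)) with timepoint columns
    ordered (T1, T2).  Pooled cell counts are sums of these rows, so any
    relabeling of the design reduces to re-summing them.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    n = data.n_participants
    num = np.zeros((n, 2))
    den = np.zeros((n, 2))
    is_mbct = np.zeros(n, dtype=bool)
    for i, p in enumerate(data.participants):
        is_mbct[i] = p.group == "MBCT"
        for j, tp in enumerate(TIMEPOINTS):
            seqs = p.sequences_at(tp)
            if metric == "recall_pct":
                num[i, j] = sum(
                    1
                    for s in seqs
                    for e in s.events
                    if e.classification == "target" and e.category == category
                )
                den[i, j] = sum(
                    data.stimulus_for(s).target_count(category) for s in seqs
                )
            else:
                rc = count_retained(retained_category_sequence(s) for s in seqs)
                if metric == "pstart":
                    num[i, j], den[i, j] = rc.starts[category], rc.n_nonempty
                elif metric == "pstay":
                    num[i, j], den[i, j] = (
                        rc.stays[category],
                        rc.transitions_from[category],
                    )
                elif metric == "pstop":
                    num[i, j], den[i, j] = rc.finals[category], rc.recalls[category]
                elif metric == "terminal":
                    num[i, j], den[i, j] = rc.finals[category], rc.n_nonempty
    return is_mbct, num, den


def _scale(metric: str) -> float:
    return 100.0 if metric == "recall_pct" else 1.0


def _observed_change(
    is_mbct: np.ndarray, num: np.ndarray, den: np.ndarray, group: str, scale: float
) -> float:
    mask = is_mbct if group == "MBCT" else ~is_mbct
    vals = []
    for j in (0, 1):
        d = den[mask, j].sum()
        if d <= 0:
            raise UndefinedStatisticError(
                f"pooled estimate undefined in cell ({group}, {TIMEPOINTS[j]})"
            )
        vals.append(scale * num[mask, j].sum() / d)
    return vals[1] - vals[0]


def change_stat(data: StudyDataset, metric: str, category: str, group: str) -> float:
    """Within-group change M(group, T2) - M(group, T1) of a pooled estimate."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    is_mbct, num, den = _participant_counts(data, metric, category)
    return _observed_change(is_mbct, num, den, group, _scale(metric))


def interaction_stat(data: StudyDataset, metric: str, category: str) -> float:
    """Difference of within-group changes, MBCT minus control."""
    is_mbct, num, den = _participant_counts(data, metric, category)
    s = _scale(metric)
    return _observed_change(is_mbct, num, den, "MBCT", s) - _observed_change(
        is_mbct, num, den, "control", s
    )


def _replicate_stats(
    num: np.ndarray,
    den: np.ndarray,
    gmask: np.ndarray,  # (m, n) True where the participant plays MBCT
    flips: np.ndarray,  # (m, n) True where the participant's timepoints swap
    effect: str,
    group: Optional[str],
    scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized statistics for m relabelings; returns (stat, valid)."""
    num_t1 = np.where(flips, num[:, 1], num[:, 0])
    den_t1 = np.where(flips, den[:, 1], den[:, 0])
    num_t2 = np.where(flips, num[:, 0], num[:, 1])
    den_t2 = np.where(flips, den[:, 0], den[:, 1])

    def cell(sel: np.ndarray, nm: np.ndarray, dn: np.ndarray):
        return (nm * sel).sum(axis=1), (dn * sel).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        if effect == "time_within_group":
            sel = gmask if group == "MBCT" else ~gmask
            n1, d1 = cell(sel, num_t1, den_t1)
            n2, d2 = cell(sel, num_t2, den_t2)
            valid = (d1 > 0) & (d2 > 0)
            stat = scale * (n2 / d2 - n1 / d1)
        else:  # interaction
            mn1, md1 = cell(gmask, num_t1, den_t1)
            mn2, md2 = cell(gmask, num_t2, den_t2)
            cn1, cd1 = cell(~gmask, num_t1, den_t1)
            cn2, cd2 = cell(~gmask, num_t2, den_t2)
            valid = (md1 > 0) & (md2 > 0) & (cd1 > 0) & (cd2 > 0)
            stat = scale * ((mn2 / md2 - mn1 / md1) - (cn2 / cd2 - cn1 / cd1))
    return stat, valid


def _tail_count(stats: np.ndarray, obs: float, sidedness: str) -> int:
    if sidedness == "two_sided":
        return int(np.sum(np.abs(stats) >= abs(obs) - _TIE_TOL))
    if sidedness == "greater":
        return int(np.sum(stats >= obs - _TIE_TOL))
    return int(np.sum(stats <= obs + _TIE_TOL))


def default_scheme(effect: str) -> PermutationScheme:
    """Label swaps used for each effect: time flips alone for within-group
    change, group permutation and time flips jointly for the interaction."""
    if effect == "time_within_group":
        return PermutationScheme(swap_time=True)
    if effect == "interaction":
        return PermutationScheme(swap_group=True, swap_time=True)
    raise ValueError(f"unknown effect {effect!r}")


def permutation_test(
    data: StudyDataset,
    metric: str,
    category: str,
    effect: str,
    group: Optional[str] = None,
    n_perm: int = 1000,
    sidedness: str = "two_sided",
    seed: int = 0,
    scheme: Optional[PermutationScheme] = None,
    max_redraw_frac: float = 0.5,
) -> PermutationResult:
    """Monte-Carlo permutation test of a pooled recall-dynamics statistic.

    Replicates whose statistic is undefined (a pooled cell emptied by the
    relabeling) are redrawn, with the redraw count reported; if more than
    ``max_redraw_frac`` of ``n_perm`` replicates need redrawing the dataset
    is considered degenerate and the test fails loudly.
    """
    if effect == "time_within_group":
        if group not in GROUPS:
            raise ValueError("time_within_group requires group='MBCT'|'control'")
    elif effect == "interaction":
        group = None
    else:
        raise ValueError(f"unknown effect {effect!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scheme is None:
        scheme = default_scheme(effect)

    is_mbct, num, den = _participant_counts(data, metric, category)
    scale = _scale(metric)
    if effect == "time_within_group":
        observed = _observed_change(is_mbct, num, den, group, scale)
    else:
        observed = _observed_change(
            is_mbct, num, den, "MBCT", scale
        ) - _observed_change(is_mbct, num, den, "control", scale)

    rng = np.random.default_rng(seed)
    n = data.n_participants
    stats = np.empty(n_perm)
    n_pending = n_perm
    n_redrawn = 0
    filled = 0
    attempts = 0
    while n_pending > 0:
        attempts += 1
        if attempts > 200:
            raise DegenerateDataError(
                "could not obtain defined permutation replicates"
            )
        if scheme.swap_time:
            flips = rng.random((n_pending, n)) < 0.5
        else:
            flips = np.zeros((n_pending, n), dtype=bool)
        if scheme.swap_group:
            order = np.argsort(rng.random((n_pending, n)), axis=1)
            gmask = is_mbct[order]
        else:
            gmask = np.broadcast_to(is_mbct, (n_pending, n))
        stat, valid = _replicate_stats(
            num, den, gmask, flips, effect, group, scale
        )
        k = int(valid.sum())
        stats[filled : filled + k] = stat[valid]
        filled += k
        n_redrawn += n_pending - k
        n_pending -= k
        if n_redrawn > max_redraw_frac * n_perm:
            raise DegenerateDataError(
                f"{n_redrawn} permutation replicates undefined "
                f"(> {max_redraw_frac:.0%} of n_perm={n_perm})"
            )

    p = (1 + _tail_count(stats, observed, sidedness)) / (1 + n_perm)
    return PermutationResult(
        metric=metric,
        category=category,
        effect=effect,
        group=group,
        observed_stat=float(observed),
        n_perm=n_perm,
        p_value=float(p),
        sidedness=sidedness,
        seed=seed,
        null_mean=float(stats.mean()),
        null_sd=float(stats.std(ddof=0)),
        n_redrawn=n_redrawn,
        method="monte_carlo",
    )


_MAX_ENUM = 5_000_000  # assignments x flips cap for exact enumeration


def exact_test(
    data: StudyDataset,
    metric: str,
    category: str,
    effect: str,
    group: Optional[str] = None,
    sidedness: str = "two_sided",
) -> PermutationResult:
    """Exhaustive-enumeration analog of :func:`permutation_test`.

    Enumerates every label assignment of the effect's scheme (identity
    included), so the p-value has no Monte-Carlo error.  Feasible only for
    small datasets; oversize requests raise :class:`CapacityError`.
    Assignments whose statistic is undefined are excluded from the
    enumeration (the analog of redrawing); if more than half are undefined
    the dataset is degenerate.
    """
    is_mbct, num, den = _participant_counts(data, metric, category)
    scale = _scale(metric)
    n = data.n_participants

    if effect == "time_within_group":
        if group not in GROUPS:
            raise ValueError("time_within_group requires group='MBCT'|'control'")
        observed = _observed_change(is_mbct, num, den, group, scale)
        members = np.flatnonzero(is_mbct if group == "MBCT" else ~is_mbct)
        m = len(members)
        if m > 16 or 2**m > _MAX_ENUM:
            raise CapacityError(f"2^{m} time-flip assignments is too many")
        codes = np.arange(2**m)
        flips = np.zeros((2**m, n), dtype=bool)
        flips[:, members] = (codes[:, None] >> np.arange(m)) & 1
        gmask = np.broadcast_to(is_mbct, flips.shape)
        stat, valid = _replicate_stats(num, den, gmask, flips, effect, group, scale)
        stats = stat[valid]
    elif effect == "interaction":
        group = None
        observed = _observed_change(
            is_mbct, num, den, "MBCT", scale
        ) - _observed_change(is_mbct, num, den, "control", scale)
        k = int(is_mbct.sum())
        n_assign = comb(n, k)
        n_flip = 2**n
        if n > 16 or n_assign * n_flip > _MAX_ENUM:
            raise CapacityError(
                f"C({n},{k}) x 2^{n} = {n_assign * n_flip} assignments is too many"
            )
        gmat = np.zeros((n_assign, n), dtype=bool)
        for i, idx in enumerate(itertools.combinations(range(n), k)):
            gmat[i, list(idx)] = True
        codes = np.arange(n_flip)
        fmat = ((codes[:, None] >> np.arange(n)) & 1).astype(bool)
        num_t1 = np.where(fmat, num[:, 1], num[:, 0])  # (n_flip, n)
        den_t1 = np.where(fmat, den[:, 1], den[:, 0])
        num_t2 = np.where(fmat, num[:, 0], num[:, 1])
        den_t2 = np.where(fmat, den[:, 0], den[:, 1])
        g = gmat.astype(float)
        c = (~gmat).astype(float)
        mn1, md1 = g @ num_t1.T, g @ den_t1.T  # (n_assign, n_flip)
        mn2, md2 = g @ num_t2.T, g @ den_t2.T
        cn1, cd1 = c @ num_t1.T, c @ den_t1.T
        cn2, cd2 = c @ num_t2.T, c @ den_t2.T
        valid = (md1 > 0) & (md2 > 0) & (cd1 > 0) & (cd2 > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = scale * ((mn2 / md2 - mn1 / md1) - (cn2 / cd2 - cn1 / cd1))
        stats = stat[valid]
    else:
        raise ValueError(f"unknown effect {effect!r}")

    n_total = valid.size
    n_valid = stats.size
    if n_valid == 0 or n_valid < n_total / 2:
        raise DegenerateDataError(
            f"{n_total - n_valid} of {n_total} enumerated assignments undefined"
        )
    p = _tail_count(stats, observed, sidedness) / n_valid
    return PermutationResult(
        metric=metric,
        category=category,
        effect=effect,
        group=group,
        observed_stat=float(observed),
        n_perm=int(n_valid),
        p_value=float(p),
        sidedness=sidedness,
        seed=None,
        null_mean=float(stats.mean()),
        null_sd=float(stats.std(ddof=0)),
        n_redrawn=int(n_total - n_valid),
        method="exact",
    )
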