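"""End-to-end orchestration: (simulate | load) -> score -> metrics -> tests.

:func:`run_full_analysis` produces a deterministic report bundle in an
output directory:

* ``events.csv`` / ``lists.csv`` — the analyzed dataset (written also when
  simulated, so every number is recomputable from emitted files),
* ``scored.csv`` — events with classification/category columns,
* ``estimates.csv`` — every pooled estimate per metric x cell x category,
  with explicit ``undefined`` rows where a pooled cell is empty,
* ``results.json`` — permutation results for each metric x category x
  effect (control change, MBCT change, interaction),
* ``table_recall_pct.csv`` — the percent-recalled grid (group x time per
  valence category),
* ``table_pvalues.csv`` — the p-value grid, rows {control, MBCT,
  interaction} per metric block, columns negative/positive; the neutral
  column lives in ``table_pvalues_appendix.csv``,
* ``changes.csv`` — T1->T2 deltas per group/category/metric,
* ``manifest.json`` — config hash, seed, package version.

:func:`run_calibration` estimates rejection rates of the interaction test
over simulated trials across a grid of planted effect sizes; the
zero-effect row is the type-I error estimate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import binomtest

from . import __version__
from .data_model import (
    CATEGORIES,
    DynamicsEstimate,
    GROUPS,
    PermutationResult,
    StudyDataset,
    TIMEPOINTS,
)
from .dynamics_metrics import pooled_metric
from .errors import (
    ConfigurationError,
    UndefinedMetricError,
    UndefinedStatisticError,
)
from .io import load_study, write_results, write_scored, write_study
from .permutation_inference import permutation_test
from .synthetic_data import (
    TrialDesign,
    baseline_params,
    effect_trial_design,
    null_trial_design,
    simulate_trial,
)

DYNAMICS_METRICS = ("pstart", "pstay", "pstop")
ALL_METRICS = ("pstart", "pstay", "pstop", "terminal", "recall_pct")


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run.

    Exactly one input source must be given: (``events_path`` and
    ``lists_path``) to load a dataset, or ``design`` to simulate one.
    """

    seed: int
    out_dir: str
    events_path: Optional[str] = None
    lists_path: Optional[str] = None
    design: Optional[dict] = None
    n_perm: int = 1000
    metrics: Sequence[str] = DYNAMICS_METRICS
    categories: Sequence[str] = CATEGORIES

    def __post_init__(self) -> None:
        have_files = self.events_path is not None or self.lists_path is not None
        have_both = self.events_path is not None and self.lists_path is not None
        if have_files and not have_both:
            raise ConfigurationError(
                "events_path and lists_path must be given together"
            )
        if have_both == (self.design is not None):
            raise ConfigurationError(
                "give exactly one input: events/lists paths or a design"
            )
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        bad = set(self.metrics) - set(ALL_METRICS)
        if bad:
            raise ConfigurationError(f"unknown metric(s) {sorted(bad)!r}")
        bad = set(self.categories) - set(CATEGORIES)
        if bad:
            raise ConfigurationError(f"unknown categor(ies) {sorted(bad)!r}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "AnalysisConfig":
        allowed = {
            "seed",
            "out_dir",
            "events_path",
            "lists_path",
            "design",
            "n_perm",
            "metrics",
            "categories",
        }
        unknown = set(cfg) - allowed
        if unknown:
            raise ConfigurationError(f"unknown config key(s) {sorted(unknown)!r}")
        if "seed" not in cfg or "out_dir" not in cfg:
            raise ConfigurationError("config requires 'seed' and 'out_dir'")
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(cfg)

    def canonical_json(self) -> str:
        payload = {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "events_path": self.events_path,
            "lists_path": self.lists_path,
            "design": self.design,
            "n_perm": self.n_perm,
            "metrics": list(self.metrics),
            "categories": list(self.categories),
        }
        return json.dumps(payload, sort_keys=True)


def design_from_dict(cfg: Optional[dict], seed: int) -> TrialDesign:
    """Build a :class:`TrialDesign` from a flat config mapping.

    Recognized keys: n_mbct, n_control, lists_per_assessment, effect
    (planted T1->T2 shift magnitude, 0 for a null design), seed.
    """
    cfg = dict(cfg or {})
    allowed = {"n_mbct", "n_control", "lists_per_assessment", "effect", "seed"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ConfigurationError(f"unknown design key(s) {sorted(unknown)!r}")
    effect = float(cfg.pop("effect", 0.0))
    cfg.setdefault("seed", seed)
    if effect == 0.0:
        return null_trial_design(**cfg)
    return effect_trial_design(effect=effect, **cfg)


@dataclass
class ReportBundle:
    """In-memory view of a completed run; files live under ``out_dir``."""

    out_dir: Path
    data: StudyDataset
    estimates: pd.DataFrame
    results: list[PermutationResult]
    recall_table: pd.DataFrame
    pvalue_table: pd.DataFrame
    pvalue_appendix: pd.DataFrame
    changes: pd.DataFrame
    manifest: dict


def _derive_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0] % 2**31)


def _all_estimates(data: StudyDataset) -> pd.DataFrame:
    rows = []
    for metric in ALL_METRICS:
        for g in GROUPS:
            for t in TIMEPOINTS:
                for c in CATEGORIES:
                    try:
                        est = pooled_metric(data, metric, g, t, (c,))[c]
                        rows.append(
                            (metric, c, g, t, est.numerator, est.denominator, est.value)
                        )
                    except UndefinedMetricError:
                        rows.append((metric, c, g, t, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows,
        columns=[
            "metric",
            "category",
            "group",
            "timepoint",
            "numerator",
            "denominator",
            "value",
        ],
    )


def run_full_analysis(config: AnalysisConfig | dict) -> ReportBundle:
    """Run the complete pipeline and write the report bundle.

    Deterministic: identical configs yield byte-identical bundles.
    Configuration errors surface before any computation starts.
    """
    if isinstance(config, dict):
        config = AnalysisConfig.from_dict(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.design is not None:
        design = design_from_dict(config.design, config.seed)
        data = simulate_trial(design)
    else:
        data = load_study(config.events_path, config.lists_path)
    write_study(data, out / "events.csv", out / "lists.csv")
    write_scored(data, out / "scored.csv")

    estimates = _all_estimates(data)
    estimates.to_csv(out / "estimates.csv", index=False, lineterminator="\n")

    results: list[PermutationResult] = []
    idx = 0
    for metric in config.metrics:
        for c in config.categories:
            jobs = [
                ("time_within_group", "control"),
                ("time_within_group", "MBCT"),
                ("interaction", None),
            ]
            for effect, group in jobs:
                try:
                    results.append(
                        permutation_test(
                            data,
                            metric,
                            c,
                            effect,
                            group=group,
                            n_perm=config.n_perm,
                            seed=_derive_seed(config.seed, idx),
                        )
                    )
                except (UndefinedStatisticError, UndefinedMetricError):
                    pass
                idx += 1
    write_results(results, out / "results.json")

    recall_rows = []
    for c in CATEGORIES:
        for g in GROUPS:
            sub = estimates.query(
                "metric == 'recall_pct' and category == @c and group == @g"
            )
            vals = {t: sub.query("timepoint == @t")["value"].iloc[0] for t in TIMEPOINTS}
            recall_rows.append((c, g, vals["T1"], vals["T2"]))
    recall_table = pd.DataFrame(
        recall_rows, columns=["category", "group", "T1", "T2"]
    )
    recall_table.to_csv(out / "table_recall_pct.csv", index=False, lineterminator="\n")

    def _p(metric: str, category: str, effect: str, group: Optional[str]):
        for r in results:
            if (
                r.metric == metric
                and r.category == category
                and r.effect == effect
                and r.group == group
            ):
                return r.p_value
        return np.nan

    def _pvalue_frame(categories: Sequence[str]) -> pd.DataFrame:
        rows = []
        for metric in config.metrics:
            for label, effect, group in (
                ("control", "time_within_group", "control"),
                ("MBCT", "time_within_group", "MBCT"),
                ("interaction", "interaction", None),
            ):
                rows.append(
                    [metric, label]
                    + [_p(metric, c, effect, group) for c in categories]
                )
        return pd.DataFrame(rows, columns=["metric", "row"] + list(categories))

    pvalue_table = _pvalue_frame(["negative", "positive"])
    pvalue_table.to_csv(out / "table_pvalues.csv", index=False, lineterminator="\n")
    pvalue_appendix = _pvalue_frame(["neutral"])
    pvalue_appendix.to_csv(
        out / "table_pvalues_appendix.csv", index=False, lineterminator="\n"
    )

    change_rows = []
    for metric in config.metrics:
        for c in CATEGORIES:
            for g in GROUPS:
                sub = estimates.query(
                    "metric == @metric and category == @c and group == @g"
                )
                v1 = sub.query("timepoint == 'T1'")["value"].iloc[0]
                v2 = sub.query("timepoint == 'T2'")["value"].iloc[0]
                change_rows.append((metric, c, g, v1, v2, v2 - v1))
    changes = pd.DataFrame(
        change_rows, columns=["metric", "category", "group", "T1", "T2", "delta"]
    )
    changes.to_csv(out / "changes.csv", index=False, lineterminator="\n")

    manifest = {
        "package": "recalldyn",
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "config_sha256": hashlib.sha256(
            config.canonical_json().encode()
        ).hexdigest(),
        "n_participants": data.n_participants,
        "n_lists": len(data.lists),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return ReportBundle(
        out_dir=out,
        data=data,
        estimates=estimates,
        results=results,
        recall_table=recall_table,
        pvalue_table=pvalue_table,
        pvalue_appendix=pvalue_appendix,
        changes=changes,
        manifest=manifest,
    )


@dataclass
class CalibrationConfig:
    """Monte-Carlo calibration/power study of the interaction test."""

    n_sims: int
    alpha: float = 0.05
    effects: Sequence[float] = (0.0,)
    metric: str = "pstay"
    category: str = "negative"
    n_perm: int = 1000
    seed: int = 0
    design: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ConfigurationError("n_sims must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.metric not in ALL_METRICS:
            raise ConfigurationError(f"unknown metric {self.metric!r}")
        if self.category not in CATEGORIES:
            raise ConfigurationError(f"unknown category {self.category!r}")


def run_calibration(config: CalibrationConfig | dict) -> pd.DataFrame:
    """Rejection rate of the interaction test per planted effect size.

    Each row reports the rejection rate at ``alpha`` with a 95% binomial
    (exact) confidence interval; the effect=0 row estimates type-I error.
    """
    if isinstance(config, dict):
        config = CalibrationConfig(**config)
    rows = []
    for ei, effect in enumerate(config.effects):
        rejections = 0
        for i in range(config.n_sims):
            trial_seed = _derive_seed(config.seed, ei * config.n_sims + i)
            base = dict(config.design)
            base["effect"] = effect
            design = design_from_dict(base, trial_seed)
            data = simulate_trial(design)
            res = permutation_test(
                data,
                config.metric,
                config.category,
                "interaction",
                n_perm=config.n_perm,
                seed=_derive_seed(trial_seed, 1),
            )
            if res.p_value <= config.alpha:
                rejections += 1
        ci = binomtest(rejections, config.n_sims).proportion_ci(0.95)
        rows.append(
            (
                effect,
                config.n_sims,
                rejections,
                rejections / config.n_sims,
                ci.low,
                ci.high,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["effect", "n_sims", "rejections", "rate", "ci_low", "ci_high"],
    )
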