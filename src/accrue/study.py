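"""Resampling-study harness.

Repeatedly mimics prospective recruitment from a fixed population: each
repetition shuffles the population, feeds the adaptive engine the shuffled
prefix (sampling without replacement, with the accrual exhausted to the
cap so every curve has the same length), and evaluates every interim model
on the permutation's suffix — the patients never used for development in
that repetition — as a holdout check on the bootstrap-corrected estimates.
Stop sizes and performance at stop are summarized by median and IQR
(linear interpolation between order statistics); average learning and
holdout curves are pointwise means across repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .adaptive import LearningCurve, derive_seed, run_adaptive
from .core_data import AccrualConfig, PatientTable, StoppingRule
from .performance import UndefinedMetricError, c_statistic, calibration_slope
from .strategies import StrategySpec, predict_lp
from .synthetic import ScenarioConfig, generate_population

__all__ = [
    "StudyConfig",
    "RepetitionResult",
    "StudySummary",
    "run_repetition",
    "run_study",
    "summarize_study",
    "compare_corrected_vs_holdout",
]


@dataclass
class StudyConfig:
    """Configuration of one resampling study (scaled-down by default)."""

    scenario: ScenarioConfig | PatientTable
    acc: AccrualConfig
    spec: StrategySpec
    rules: tuple[StoppingRule, ...]
    repetitions: int = 20
    root_seed: int = 0

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class RepetitionResult:
    curve: LearningCurve
    holdout: pd.DataFrame  # per-assessment: n, holdout_auc, holdout_slope
    holdout_n: int = 0  # patients never used for development in this repetition


def run_repetition(
    pop: PatientTable,
    acc: AccrualConfig,
    spec: StrategySpec,
    rules: Sequence[StoppingRule],
    rep_seed: int,
) -> RepetitionResult:
    """One repetition: shuffle, accrue to the cap, evaluate on the suffix.

    The permutation's first ``acc.n_max`` rows form the accrual stream (the
    development prefix grows inside it); the remaining rows are the holdout
    and never enter development, so development and holdout partition the
    population. Deterministic in ``rep_seed``.
    """
    if pop.n < acc.n_max + 1:
        raise ValueError(
            f"population of {pop.n} cannot supply n_max={acc.n_max} plus a holdout"
        )
    rng = np.random.default_rng(rep_seed)
    perm = rng.permutation(pop.n)
    stream = pop.take(perm[: acc.n_max])
    holdout = pop.take(perm[acc.n_max:])
    curve = run_adaptive(stream, spec, replace(acc, seed=rep_seed), rules, exhaust=True)

    rows = []
    for a in curve.assessments:
        auc = slope = np.nan
        if a.model is not None:
            try:
                lp = predict_lp(a.model, holdout)
                auc = c_statistic(lp, holdout.y)
                slope = calibration_slope(lp, holdout.y)
            except UndefinedMetricError:
                pass
        rows.append({"n": a.n, "holdout_auc": auc, "holdout_slope": slope})
    return RepetitionResult(curve=curve, holdout=pd.DataFrame(rows),
                            holdout_n=holdout.n)


def run_study(cfg: StudyConfig) -> list[RepetitionResult]:
    """All repetitions of a study; repetition i is keyed by (root_seed, i)."""
    pop = (
        generate_population(cfg.scenario)
        if isinstance(cfg.scenario, ScenarioConfig)
        else cfg.scenario
    )
    results = []
    for i in range(cfg.repetitions):
        results.append(
            run_repetition(pop, cfg.acc, cfg.spec, cfg.rules, derive_seed(cfg.root_seed, i))
        )
    return results


def _median_iqr(x: Sequence[float]) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(np.asarray(x, dtype=float), [25, 50, 75])
    return float(med), float(q1), float(q3)


@dataclass
class StudySummary:
    """Median/IQR summaries per rule plus average learning/holdout curves."""

    per_rule: dict[str, dict[str, object]]
    curve: pd.DataFrame  # per-n means: auc_corrected, auc_optimism, slope_corrected
    holdout_curve: pd.DataFrame  # per-n means: holdout_auc, holdout_slope
    repetitions: int


def summarize_study(results: Sequence[RepetitionResult]) -> StudySummary:
    """Summarize a study: per-rule stop statistics and average curves.

    Repetitions where a rule was never met are reported as censored at the
    cap and excluded from the stop-size median/IQR.
    """
    if not results:
        raise ValueError("at least one repetition is required")
    rules = list(results[0].curve.stop_n)
    per_rule: dict[str, dict[str, object]] = {}
    for rn in rules:
        stops, epps, aucs, slopes = [], [], [], []
        censored = 0
        for r in results:
            sn = r.curve.stop_n[rn]
            if sn is None:
                censored += 1
                continue
            stops.append(sn)
            a = next(x for x in r.curve.assessments if x.n == sn)
            npar = a.model.n_params if a.model is not None else np.nan
            epps.append(a.perf.events / npar)
            aucs.append(a.perf.auc_corrected)
            slopes.append(a.perf.slope_corrected)
        entry: dict[str, object] = {"censored_at_cap": censored, "n_met": len(stops)}
        if stops:
            for key, vals in [
                ("stop_n", stops),
                ("epp", epps),
                ("auc_corrected", aucs),
                ("slope_corrected", slopes),
            ]:
                med, q1, q3 = _median_iqr(vals)
                entry[key] = {"median": med, "q1": q1, "q3": q3}
        per_rule[rn] = entry

    frames = []
    for r in results:
        f = r.curve.to_frame()[
            ["n", "auc_apparent", "auc_corrected", "auc_optimism",
             "slope_apparent", "slope_corrected"]
        ]
        frames.append(f.set_index("n"))
    curve = pd.concat(frames).groupby(level=0).mean().reset_index()
    hold = pd.concat([r.holdout.set_index("n") for r in results])
    holdout_curve = hold.groupby(level=0).mean().reset_index()
    return StudySummary(
        per_rule=per_rule,
        curve=curve,
        holdout_curve=holdout_curve,
        repetitions=len(results),
    )


def compare_corrected_vs_holdout(summary: StudySummary) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-assessment (mean corrected - mean holdout) differences.

    Also reports the maximum absolute difference over the final third of
    the curve, where internal validation and holdout evaluation are
    expected to agree closely.
    """
    m = summary.curve.merge(summary.holdout_curve, on="n")
    m["d_auc"] = m["auc_corrected"] - m["holdout_auc"]
    m["d_slope"] = m["slope_corrected"] - m["holdout_slope"]
    tail = m.iloc[2 * len(m) // 3:]
    stats = {
        "max_abs_d_auc_final_third": float(tail["d_auc"].abs().max()),
        "max_abs_d_slope_final_third": float(tail["d_slope"].abs().max()),
    }
    return m[["n", "d_auc", "d_slope"]], stats
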