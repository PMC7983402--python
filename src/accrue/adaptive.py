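"""Adaptive sample-size engine.

Patients are accrued in batches on top of a starting set; after every batch
the prespecified strategy is refit, internally validated with the enhanced
bootstrap, and the stopping rules are evaluated on the bootstrap-corrected
calibration slope and AUC optimism. A rule is satisfied once its (inclusive)
thresholds are met on the required number of consecutive assessments; the
model fitted at the assessment completing the rule is the final model for
that rule. With ``exhaust=True`` accrual continues to the cap even after
every rule is met, producing a fixed-length learning curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import AccrualConfig, PatientTable, StoppingRule, ValidationError
from .performance import BootstrapError, PerfEstimate, UndefinedMetricError, enhanced_bootstrap
from .strategies import FitError, FittedModel, StrategySpec

__all__ = [
    "Assessment",
    "LearningCurve",
    "evaluate_rule",
    "run_adaptive",
    "derive_seed",
]

# rule_status values
MET_CONSECUTIVE = "met_consecutive"
MET_INSTANTANEOUS = "met_instantaneous"
NOT_MET = "not_met"
UNDEFINED = "undefined"


def derive_seed(*key: int) -> int:
    """Deterministic sub-seed (< 2^31) from an integer key path."""
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] % (2**31))


@dataclass
class Assessment:
    """One point on the learning curve."""

    k: int
    n: int
    perf: PerfEstimate | None
    rule_status: dict[str, str] = field(default_factory=dict)
    model: FittedModel | None = None
    note: str = ""


def _instantaneous(perf: PerfEstimate, rule: StoppingRule) -> bool:
    # thresholds are inclusive: "at least" 0.9 slope, "at most" 0.02 optimism
    return (
        perf.slope_corrected >= rule.slope_min
        and perf.auc_optimism <= rule.optimism_max
    )


def evaluate_rule(history: Sequence[Assessment], rule: StoppingRule) -> str:
    """Status of ``rule`` at the latest assessment in ``history``.

    ``met_consecutive`` requires the last ``rule.consecutive`` assessments to
    all meet the instantaneous thresholds; an undefined assessment (failed
    fit or metric) breaks the run and resets the count.
    """
    if not history:
        raise ValueError("history must be nonempty")
    last = history[-1]
    if last.perf is None:
        return UNDEFINED
    if not _instantaneous(last.perf, rule):
        return NOT_MET
    if len(history) < rule.consecutive:
        return MET_INSTANTANEOUS
    window = history[-rule.consecutive:]
    if all(a.perf is not None and _instantaneous(a.perf, rule) for a in window):
        return MET_CONSECUTIVE
    return MET_INSTANTANEOUS


@dataclass
class LearningCurve:
    """Ordered assessments plus per-rule stopping decisions."""

    assessments: list[Assessment]
    stop_n: dict[str, int | None]
    final_model: dict[str, FittedModel | None]
    truncated_at: int | None

    def to_frame(self) -> pd.DataFrame:
        """One row per assessment (for CSV export and plotting)."""
        rows = []
        for a in self.assessments:
            row: dict[str, object] = {"k": a.k, "n": a.n}
            if a.perf is not None:
                p = a.perf
                npar = a.model.n_params if a.model is not None else np.nan
                row.update(
                    events=p.events,
                    epp=p.events / npar if npar else np.nan,
                    auc_apparent=p.auc_apparent,
                    auc_corrected=p.auc_corrected,
                    auc_optimism=p.auc_optimism,
                    slope_apparent=p.slope_apparent,
                    slope_corrected=p.slope_corrected,
                    B_used=p.B_used,
                )
            else:
                row["note"] = a.note
            for rn, st in a.rule_status.items():
                row[f"status_{rn}"] = st
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_json(self) -> str:
        out = {
            "stop_n": self.stop_n,
            "truncated_at": self.truncated_at,
            "final_models": {
                rn: (json.loads(m.to_json()) if m is not None else None)
                for rn, m in self.final_model.items()
            },
        }
        return json.dumps(out, indent=2)


def run_adaptive(
    source: PatientTable,
    spec: StrategySpec,
    acc: AccrualConfig,
    rules: Sequence[StoppingRule],
    exhaust: bool = True,
    n0: int | None = None,
) -> LearningCurve:
    """Run the adaptive procedure on an ordered patient stream.

    The development set grows by prefix: the first ``n_start`` rows, then
    ``n_add`` more per assessment (the resampling harness supplies a
    shuffled stream; in a prospective study the stream is recruitment
    order). Assessment ``k`` keys its bootstrap with a sub-seed derived from
    ``(acc.seed, k)``, so the whole curve is a pure function of
    (stream, spec, accrual config, rules). Assessments whose fit or metrics
    fail are recorded with status ``undefined`` and never count toward the
    consecutive requirement. With ``exhaust=False`` the run stops at the
    first assessment where any rule is satisfied.

    ``n0``, when given, is the a priori fixed sample-size estimate: rule
    satisfaction is not acted on (no stop recorded) before ``n`` reaches
    it. By default the initial estimate is advisory only.
    """
    if not rules:
        raise ValueError("at least one stopping rule is required")
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        raise ValueError("stopping rules must have unique names")
    if source.n < acc.n_start:
        raise ValidationError(
            f"stream has {source.n} rows, fewer than n_start={acc.n_start}"
        )

    sizes = [n for n in acc.assessment_sizes() if n <= source.n]
    history: list[Assessment] = []
    stop_n: dict[str, int | None] = {r.name: None for r in rules}
    final_model: dict[str, FittedModel | None] = {r.name: None for r in rules}
    any_ok = False

    for k, n in enumerate(sizes, start=1):
        dev = source.head(n)
        a = Assessment(k=k, n=n, perf=None)
        try:
            perf, model, _ = enhanced_bootstrap(
                dev, spec, B=acc.B, seed=derive_seed(acc.seed, k), return_model=True
            )
            a.perf = perf
            a.model = model
            any_ok = True
        except (UndefinedMetricError, BootstrapError, ValidationError, FitError) as exc:
            a.note = str(exc)
        history.append(a)
        for r in rules:
            st = evaluate_rule(history, r)
            a.rule_status[r.name] = st
            if (
                st == MET_CONSECUTIVE
                and stop_n[r.name] is None
                and (n0 is None or n >= n0)
            ):
                stop_n[r.name] = n
                final_model[r.name] = a.model
        if not exhaust and any(stop_n[r.name] is not None for r in rules):
            break

    if not any_ok:
        raise RuntimeError(
            "every assessment failed: "
            + "; ".join(f"n={a.n}: {a.note}" for a in history)
        )
    truncated = None if all(v is not None for v in stop_n.values()) else sizes[-1]
    return LearningCurve(
        assessments=history,
        stop_n=stop_n,
        final_model=final_model,
        truncated_at=truncated,
    )
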