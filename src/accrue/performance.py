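"""Performance measures and Harrell's enhanced bootstrap.

Discrimination is the c-statistic (AUC): the probability that a randomly
chosen event patient receives a higher score than a randomly chosen
non-event patient, ties counted one half. Calibration is the slope of a
logistic refit of the outcome on the model's linear predictor: a slope below
1 means the estimated risks are too extreme (overfitting), above 1 too
modest.

The enhanced bootstrap estimates optimism by refitting the *complete*
modeling strategy on each resample (model ``M_B``), recording its
performance on the resample (``PM_B``) and on the original development data
(``PM_O``); the mean of ``PM_B - PM_O`` over replicates is subtracted from
the apparent performance of the development model ``M_D`` to give
bootstrap-corrected estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core_data import PatientTable, ValidationError
from .strategies import FittedModel, StrategySpec, apply_strategy, newton_logistic, predict_lp

__all__ = [
    "PerfEstimate",
    "UndefinedMetricError",
    "BootstrapError",
    "c_statistic",
    "calibration_fit",
    "calibration_slope",
    "enhanced_bootstrap",
]


class UndefinedMetricError(ValueError):
    """The requested performance measure is undefined on these inputs."""


class BootstrapError(RuntimeError):
    """Every bootstrap replicate failed; no optimism estimate available."""


def c_statistic(scores: np.ndarray, y: np.ndarray) -> float:
    """Concordance probability with the Mann-Whitney tie convention.

    Invariant under any strictly increasing transform of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("c-statistic needs both outcome classes")
    r = rankdata(scores)  # average ranks handle ties as 1/2 wins
    u = float(r[y == 1].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def calibration_fit(lp: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(intercept, slope) of the maximum-likelihood logistic calibration fit.

    The slope is the calibration slope; the intercept is computed for
    completeness but plays no role in the stopping rules (it is of little
    interest at internal validation).
    """
    lp = np.asarray(lp, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(y[~np.isnan(y)]).size < 2:
        raise UndefinedMetricError("calibration fit needs both outcome classes")
    if np.ptp(lp) < 1e-12:
        raise UndefinedMetricError("linear predictor has zero variance")
    X = np.column_stack([np.ones_like(lp), lp])
    beta, info = newton_logistic(X, y, firth=False)
    if not info["converged"]:
        raise UndefinedMetricError(
            "calibration fit did not converge"
            + (" (separation)" if info["separation"] else "")
        )
    return float(beta[0]), float(beta[1])


def calibration_slope(lp: np.ndarray, y: np.ndarray) -> float:
    """Calibration slope of a linear predictor against observed outcomes."""
    return calibration_fit(lp, y)[1]


@dataclass(frozen=True)
class PerfEstimate:
    """Apparent / optimism / corrected performance from one assessment."""

    n: int
    events: int
    auc_apparent: float
    auc_corrected: float
    auc_optimism: float
    slope_apparent: float
    slope_corrected: float
    B_requested: int
    B_used: int
    failed_replicates: int
    low_replicates: bool = False

    def __post_init__(self) -> None:
        if self.B_used != self.B_requested - self.failed_replicates:
            raise ValueError("B_used must equal B_requested - failed_replicates")


def _perf_on(model: FittedModel, t: PatientTable) -> tuple[float, float]:
    lp = predict_lp(model, t)
    return c_statistic(lp, t.y), calibration_slope(lp, t.y)


def enhanced_bootstrap(
    t: PatientTable,
    spec: StrategySpec,
    B: int,
    seed: int,
    fit_fn=None,
    return_model: bool = False,
    stratified: bool = False,
):
    """Bootstrap-corrected AUC and calibration slope for one strategy.

    Each replicate draws ``n`` rows with replacement, reruns the complete
    strategy (including spline-knot re-estimation, re-selection and — when
    configured — re-imputation) and contributes ``PM_B - PM_O`` to the
    optimism for both measures. Resampling is plain row-wise i.i.d. by
    default; ``stratified=True`` resamples within outcome classes
    (preserving the event count), useful only for degenerate tiny-n cases
    where single-class resamples would dominate. The apparent calibration slope of ``M_D`` is
    obtained by refitting the calibration model, not assumed to equal 1, so
    penalized estimators are handled correctly. Replicates whose refit fails
    (non-convergence, single-class resample, undefined metric) are dropped
    and counted; using fewer than half the requested replicates flags the
    estimate.

    Replicate ``b`` draws from an rng keyed by ``(seed, b)``, so results do
    not depend on execution order.

    ``fit_fn(table, rng_key) -> (model, table_used)`` can replace the
    strategy (testing hook).
    """
    if B < 1:
        raise ValueError("B must be >= 1")

    def default_fit(tbl: PatientTable, key: tuple[int, ...]):
        return apply_strategy(tbl, spec, seed=list(key))

    fit = fit_fn or default_fit

    model_d, t_dev = fit(t, (seed, 0))
    if not model_d.converged:
        raise UndefinedMetricError(f"development fit failed: {model_d.diagnostic}")
    auc_app, slope_app = _perf_on(model_d, t_dev)

    n = t.n
    opt_auc: list[float] = []
    opt_slope: list[float] = []
    failed = 0
    idx_1 = np.flatnonzero(t.y == 1)
    idx_0 = np.flatnonzero(t.y == 0)
    for b in range(1, B + 1):
        rng = np.random.default_rng([seed, b])
        if stratified:
            idx = np.concatenate(
                [rng.choice(idx_1, len(idx_1)), rng.choice(idx_0, len(idx_0))]
            )
        else:
            idx = rng.integers(0, n, n)
        boot = t.take(idx)
        try:
            if not boot.both_classes():
                raise UndefinedMetricError("single-class resample")
            model_b, boot_dev = fit(boot, (seed, b))
            if not model_b.converged:
                raise UndefinedMetricError(model_b.diagnostic or "fit failed")
            auc_b, slope_b = _perf_on(model_b, boot_dev)
            auc_o, slope_o = _perf_on(model_b, t_dev)
        except (UndefinedMetricError, ValidationError):
            failed += 1
            continue
        opt_auc.append(auc_b - auc_o)
        opt_slope.append(slope_b - slope_o)

    used = B - failed
    if used == 0:
        raise BootstrapError(f"all {B} bootstrap replicates failed")
    low = used < 0.5 * B
    auc_optimism = float(np.mean(opt_auc))
    slope_optimism = float(np.mean(opt_slope))
    perf = PerfEstimate(
        n=t.n,
        events=t.n_events,
        auc_apparent=auc_app,
        auc_corrected=auc_app - auc_optimism,
        auc_optimism=auc_optimism,
        slope_apparent=slope_app,
        slope_corrected=slope_app - slope_optimism,
        B_requested=B,
        B_used=used,
        failed_replicates=failed,
        low_replicates=low,
    )
    if return_model:
        return perf, model_d, t_dev
    return perf
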