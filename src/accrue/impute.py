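"""Stochastic imputation by fully conditional specification (FCS).

Each incomplete predictor is regressed on all other predictors plus the
outcome, and missing cells are filled with a single stochastic draw from the
fitted conditional model (normal noise for continuous, Bernoulli for binary,
multinomial for categorical). The chained loop cycles through incomplete
columns a fixed number of times. Observed cells are never touched and the
outcome must be fully observed.

``mi_in_bootstrap`` embeds multiple imputation inside the enhanced
bootstrap: the development data are imputed m times for apparent
performance, and every bootstrap replicate is re-imputed m times, averaging
the performance measures across imputations before the optimism difference
is taken.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .core_data import PatientTable, ValidationError
from .strategies import FitError, StrategySpec, newton_logistic

__all__ = ["fcs_impute_single", "mi_in_bootstrap", "ImputationError"]

MAX_MISSING_FRACTION = 0.95


class ImputationError(RuntimeError):
    pass


def _predictor_matrix(
    t: PatientTable, work: dict[str, np.ndarray], exclude: str
) -> np.ndarray:
    """Numeric matrix of all predictors except ``exclude``, plus the outcome."""
    cols: list[np.ndarray] = [np.ones(t.n)]
    for m in t.meta:
        if m.name == exclude:
            continue
        v = work[m.name]
        if m.vtype == "categorical":
            for j in range(1, len(m.levels)):
                cols.append((v == j).astype(float))
        else:
            cols.append(v)
    cols.append(t.y.astype(float))
    return np.column_stack(cols)


def fcs_impute_single(
    t: PatientTable, seed: int | Sequence[int], cycles: int = 10
) -> PatientTable:
    """Complete a table with one stochastic FCS draw per missing cell."""
    if not t.has_missing():
        return t
    incomplete = [m for m in t.meta if t.missing[m.name].any()]
    for m in incomplete:
        frac = t.missing[m.name].mean()
        if frac > MAX_MISSING_FRACTION:
            raise ImputationError(
                f"column {m.name!r} is {frac:.0%} missing; cannot impute"
            )
    if not any(not t.missing[m.name].any() for m in t.meta):
        # all columns incomplete is allowed by FCS, but require outcome + at
        # least one complete column for a stable start
        raise ImputationError("at least one complete predictor column is required")

    rng = np.random.default_rng(seed)
    work = {m.name: t.columns[m.name].copy() for m in t.meta}

    # initial fill: marginal draws from the observed values of each column
    for m in incomplete:
        mask = t.missing[m.name]
        obs = work[m.name][~mask]
        work[m.name][mask] = rng.choice(obs, size=int(mask.sum()), replace=True)

    for _ in range(cycles):
        for m in incomplete:
            mask = t.missing[m.name]
            X = _predictor_matrix(t, work, exclude=m.name)
            Xo, Xm = X[~mask], X[mask]
            vo = work[m.name][~mask]
            if m.vtype == "continuous":
                beta, res, *_ = np.linalg.lstsq(Xo, vo, rcond=None)
                fitted = Xo @ beta
                dof = max(len(vo) - Xo.shape[1], 1)
                sigma = float(np.sqrt(np.sum((vo - fitted) ** 2) / dof))
                draw = Xm @ beta + rng.normal(0.0, sigma, size=len(Xm))
                draw = np.clip(draw, vo.min(), vo.max())
            elif m.vtype == "binary":
                if np.unique(vo).size < 2:
                    p = np.full(len(Xm), float(vo.mean()))
                else:
                    try:
                        b, info = newton_logistic(Xo, vo, firth=True, max_iter=50)
                        p = expit(Xm @ b)
                    except FitError:
                        p = np.full(len(Xm), float(vo.mean()))
                draw = (rng.random(len(Xm)) < p).astype(float)
            else:  # categorical: multinomial logistic draw
                if np.unique(vo).size < 2:
                    probs = np.zeros((len(Xm), len(m.levels)))
                    probs[:, int(vo[0])] = 1.0
                    classes = np.arange(len(m.levels))
                else:
                    # standardize so the lbfgs solver converges on raw-scale
                    # predictors (mg/dL etc.); the family is unchanged
                    mu = Xo[:, 1:].mean(axis=0)
                    sd = Xo[:, 1:].std(axis=0)
                    sd[sd == 0] = 1.0
                    clf = LogisticRegression(max_iter=1000)
                    clf.fit((Xo[:, 1:] - mu) / sd, vo.astype(int))
                    probs = clf.predict_proba((Xm[:, 1:] - mu) / sd)
                    classes = clf.classes_
                u = rng.random(len(Xm))
                cum = np.cumsum(probs, axis=1)
                pick = (u[:, None] > cum).sum(axis=1)
                draw = classes[np.minimum(pick, len(classes) - 1)].astype(float)
            work[m.name][mask] = draw

    missing = {m.name: np.zeros(t.n, dtype=bool) for m in t.meta}
    return t.with_columns(work, missing)


def mi_in_bootstrap(
    t: PatientTable, spec: StrategySpec, B: int, m: int, seed: int
):
    """Enhanced bootstrap with multiple imputation embedded in each replicate.

    Apparent performance averages the AUC and calibration slope over ``m``
    completed versions of the development data (model fit per imputation).
    Each bootstrap replicate resamples the incomplete rows, imputes the
    *replicate* ``m`` times, and averages ``PM_B`` (on the completed
    replicate) and ``PM_O`` (model from completed replicate j applied to
    completed development version j) across imputations before the optimism
    difference is taken. On a complete table this reduces exactly to the
    plain enhanced bootstrap.
    """
    from .performance import (
        BootstrapError,
        PerfEstimate,
        UndefinedMetricError,
        c_statistic,
        calibration_slope,
        enhanced_bootstrap,
    )
    from .strategies import apply_strategy, predict_lp

    if m < 1:
        raise ValueError("m must be >= 1")
    if not t.has_missing():
        return enhanced_bootstrap(t, spec, B, seed)

    def strat(tbl: PatientTable):
        model, _ = apply_strategy(tbl, spec)  # tbl is complete here
        if not model.converged:
            raise UndefinedMetricError(model.diagnostic or "fit failed")
        return model

    dev_imps = [fcs_impute_single(t, [seed, 0, j]) for j in range(m)]
    dev_models = [strat(dj) for dj in dev_imps]
    auc_app = float(np.mean(
        [c_statistic(predict_lp(md, dj), dj.y) for md, dj in zip(dev_models, dev_imps)]
    ))
    slope_app = float(np.mean(
        [calibration_slope(predict_lp(md, dj), dj.y) for md, dj in zip(dev_models, dev_imps)]
    ))

    opt_auc: list[float] = []
    opt_slope: list[float] = []
    failed = 0
    n = t.n
    for b in range(1, B + 1):
        rng = np.random.default_rng([seed, b])
        idx = rng.integers(0, n, n)
        boot = t.take(idx)
        try:
            if not boot.both_classes():
                raise UndefinedMetricError("single-class resample")
            aucs_b, slopes_b, aucs_o, slopes_o = [], [], [], []
            for j in range(m):
                bj = fcs_impute_single(boot, [seed, b, j])
                mj = strat(bj)
                lp_b = predict_lp(mj, bj)
                aucs_b.append(c_statistic(lp_b, bj.y))
                slopes_b.append(calibration_slope(lp_b, bj.y))
                lp_o = predict_lp(mj, dev_imps[j])
                aucs_o.append(c_statistic(lp_o, dev_imps[j].y))
                slopes_o.append(calibration_slope(lp_o, dev_imps[j].y))
        except (UndefinedMetricError, ValidationError, ImputationError):
            failed += 1
            continue
        opt_auc.append(float(np.mean(aucs_b)) - float(np.mean(aucs_o)))
        opt_slope.append(float(np.mean(slopes_b)) - float(np.mean(slopes_o)))

    used = B - failed
    if used == 0:
        raise BootstrapError(f"all {B} bootstrap replicates failed")
    auc_optimism = float(np.mean(opt_auc))
    slope_optimism = float(np.mean(opt_slope))
    return PerfEstimate(
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
        low_replicates=used < 0.5 * B,
    )
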