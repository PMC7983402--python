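"""Prespecified modeling strategies for binary risk models.

Four strategies are supported, each a deterministic map from a development
dataset to a fitted logistic model:

* plain maximum-likelihood logistic regression on the prespecified predictors;
* the same with restricted cubic splines (3 knots, one extra parameter per
  spline-flagged continuous predictor) for possibly nonlinear effects;
* Firth's penalized likelihood, which removes the first-order bias of the MLE
  and yields finite coefficients under separation;
* backward elimination at alpha = 0.05 with a forced-in set that can never be
  removed, using block likelihood-ratio tests so dummy and spline column
  groups enter and leave together.

Fitting is a hand-written Newton/IRLS iteration (the internal-validation
bootstrap refits the complete strategy thousands of times, so the solver is
kept lean); convergence is declared when the relative change in the
(penalized) log-likelihood falls below 1e-8.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.special import expit
from scipy.stats import chi2

from .core_data import PatientTable, ValidationError

__all__ = [
    "StrategySpec",
    "FittedModel",
    "FitError",
    "rcs_basis",
    "spline_knots",
    "make_recipe",
    "build_design",
    "fit_mle_logistic",
    "fit_firth_logistic",
    "backward_eliminate",
    "apply_strategy",
    "predict_lp",
    "newton_logistic",
]

ESTIMATORS = ("mle", "firth")
SELECTIONS = ("none", "backward")
IMPUTATIONS = ("none", "single_fcs", "mi_in_bootstrap")


class FitError(RuntimeError):
    """Model fitting could not proceed (rank deficiency, degenerate data)."""


@dataclass(frozen=True)
class StrategySpec:
    """A complete prespecified modeling recipe.

    The recipe must be fixed before data collection; the enhanced bootstrap
    re-runs *all* of it (spline-knot estimation, variable selection and,
    when configured, imputation) on every resample.
    """

    estimator: str = "mle"
    use_splines: bool = False
    spline_knots: int = 3
    selection: str = "none"
    alpha: float = 0.05
    forced: frozenset[str] = frozenset()
    imputation: str = "none"
    m: int = 5

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}")
        if self.selection not in SELECTIONS:
            raise ValueError(f"selection must be one of {SELECTIONS}")
        if self.imputation not in IMPUTATIONS:
            raise ValueError(f"imputation must be one of {IMPUTATIONS}")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.spline_knots != 3:
            raise ValueError("only 3-knot restricted cubic splines are supported")
        object.__setattr__(self, "forced", frozenset(self.forced))


# ---------------------------------------------------------------------------
# Restricted cubic spline basis (3 knots -> one extra column)
# ---------------------------------------------------------------------------

def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Restricted-cubic-spline basis column for 3 knots ``t1 < t2 < t3``.

        s(x) = [ (x-t1)+^3 - (x-t2)+^3 (t3-t1)/(t3-t2)
                          + (x-t3)+^3 (t2-t1)/(t3-t2) ] / (t3-t1)^2

    ``s`` is zero for x <= t1 and linear for x >= t3, so the expanded
    predictor (x, s(x)) is linear beyond the boundary knots.
    """
    t1, t2, t3 = (float(k) for k in knots)
    if not (t1 < t2 < t3):
        raise ValueError(f"knots must be strictly increasing, got {knots}")
    x = np.asarray(x, dtype=float)
    pos = lambda v: np.maximum(v, 0.0) ** 3
    s = (
        pos(x - t1)
        - pos(x - t2) * (t3 - t1) / (t3 - t2)
        + pos(x - t3) * (t2 - t1) / (t3 - t2)
    ) / (t3 - t1) ** 2
    return s


def spline_knots(x: np.ndarray, quantiles=(0.10, 0.50, 0.90)) -> tuple[float, ...] | None:
    """Empirical knots at the 10/50/90th percentiles of the observed values.

    Returns ``None`` when the quantiles tie (degenerate spread), in which
    case the caller falls back to a linear term.
    """
    obs = np.asarray(x, dtype=float)
    obs = obs[~np.isnan(obs)]
    k = tuple(float(q) for q in np.quantile(obs, quantiles))
    if not (k[0] < k[1] < k[2]):
        return None
    return k


# ---------------------------------------------------------------------------
# Design recipes: per-predictor expansion with frozen knots / level coding
# ---------------------------------------------------------------------------
# Entry forms:
#   ("identity", name)
#   ("spline",   name, (t1, t2, t3))       -> columns name, name~rcs
#   ("dummies",  name, levels)             -> columns name=level for levels[1:]

Recipe = tuple[tuple, ...]


def make_recipe(
    t: PatientTable, spec: StrategySpec, predictors: Sequence[str] | None = None
) -> Recipe:
    """Build the design recipe for the given data, estimating spline knots."""
    names = list(predictors) if predictors is not None else list(t.names)
    entries: list[tuple] = []
    for name in names:
        m = t.meta_for(name)
        if m.vtype == "categorical":
            entries.append(("dummies", name, m.levels))
        elif spec.use_splines and m.spline:
            knots = spline_knots(t.columns[name])
            if knots is None:
                entries.append(("identity", name))  # degenerate spread: linear
            else:
                entries.append(("spline", name, knots))
        else:
            entries.append(("identity", name))
    return tuple(entries)


def recipe_columns(recipe: Recipe) -> list[str]:
    cols: list[str] = []
    for entry in recipe:
        kind, name = entry[0], entry[1]
        if kind == "identity":
            cols.append(name)
        elif kind == "spline":
            cols.extend([name, f"{name}~rcs"])
        elif kind == "dummies":
            cols.extend(f"{name}={lev}" for lev in entry[2][1:])
        else:  # pragma: no cover
            raise ValueError(f"unknown recipe entry {entry}")
    return cols


def build_design(t: PatientTable, recipe: Recipe) -> tuple[np.ndarray, list[str]]:
    """Expand a patient table into the numeric design matrix of a recipe.

    Spline knots and dummy codings come from the recipe, never re-estimated,
    so a model can be applied unchanged to new data.
    """
    blocks: list[np.ndarray] = []
    for entry in recipe:
        kind, name = entry[0], entry[1]
        col = t.columns[name]
        if np.isnan(col).any():
            raise ValidationError(
                f"column {name!r} has missing values; impute before fitting"
            )
        if kind == "identity":
            blocks.append(col[:, None])
        elif kind == "spline":
            blocks.append(np.column_stack([col, rcs_basis(col, entry[2])]))
        elif kind == "dummies":
            levels = entry[2]
            table_levels = t.meta_for(name).levels
            codes = col.astype(int)
            labels = [table_levels[c] for c in codes]
            idx = []
            lut = {lev: i for i, lev in enumerate(levels)}
            for lab in labels:
                if lab not in lut:
                    raise ValidationError(
                        f"column {name!r}: level {lab!r} unseen at fit time"
                    )
                idx.append(lut[lab])
            idx = np.asarray(idx)
            dm = np.zeros((t.n, len(levels) - 1))
            for j in range(1, len(levels)):
                dm[:, j - 1] = idx == j
            blocks.append(dm)
        else:  # pragma: no cover
            raise ValueError(f"unknown recipe entry {entry}")
    X = np.hstack(blocks) if blocks else np.empty((t.n, 0))
    return X, recipe_columns(recipe)


# ---------------------------------------------------------------------------
# Newton / IRLS solver for (penalized) logistic likelihoods
# ---------------------------------------------------------------------------

def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def newton_logistic(
    X: np.ndarray,
    y: np.ndarray,
    firth: bool = False,
    tol: float = 1e-8,
    max_iter: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Newton iteration for the logistic (or Jeffreys-penalized) likelihood.

    ``X`` must already contain the intercept column. For ``firth=True`` the
    objective is ``ll + 0.5 log det I(beta)`` and the score is hat-value
    modified: ``sum_i (y_i - p_i + h_i (1/2 - p_i)) x_i``. Step-halving
    guards every update; convergence is a relative objective change < tol.

    Returns ``(beta, info)`` with ``info`` keys ``converged``, ``n_iter``,
    ``loglik`` (unpenalized), ``objective`` and ``separation``.
    """
    n, k = X.shape
    if max_iter is None:
        max_iter = 250 if firth else 100
    beta = np.zeros(k)
    ybar = min(max(float(np.mean(y)), 1e-8), 1 - 1e-8)
    # Start the intercept at logit(mean) if an intercept-like column leads.
    if np.all(X[:, 0] == 1.0):
        beta[0] = math.log(ybar / (1 - ybar))

    def objective(b: np.ndarray) -> tuple[float, float]:
        eta = X @ b
        ll = _loglik(y, eta)
        if not firth:
            return ll, ll
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        Xw = X * np.sqrt(w)[:, None]
        sign, logdet = np.linalg.slogdet(Xw.T @ Xw)
        if sign <= 0:
            return ll, -np.inf
        return ll, ll + 0.5 * logdet

    ll, obj = objective(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        Xw = X * np.sqrt(w)[:, None]
        H = Xw.T @ Xw
        try:
            c = cho_factor(H)
        except LinAlgError as exc:
            raise FitError("information matrix is singular") from exc
        if firth:
            h = np.einsum("ij,ji->i", Xw, cho_solve(c, Xw.T))
            score = X.T @ (y - p + h * (0.5 - p))
        else:
            score = X.T @ (y - p)
        step = cho_solve(c, score)
        # step-halving: require the objective not to decrease
        scale = 1.0
        for _ in range(32):
            cand = beta + scale * step
            ll_new, obj_new = objective(cand)
            if obj_new >= obj - 1e-12:
                break
            scale *= 0.5
        else:
            break
        delta = abs(obj_new - obj)
        moved = float(np.max(np.abs(scale * step)))
        beta, ll, obj = cand, ll_new, obj_new
        # objective-flatness alone can leave ~1e-4 parameter error near the
        # optimum, so require the accepted Newton step to be tiny as well
        if delta < tol * (abs(obj) + tol) and moved < 1e-7:
            converged = True
            break

    eta = X @ beta
    p = expit(eta)
    separation = bool(
        np.all(p[y == 1] > 1 - 1e-6) and np.all(p[y == 0] < 1e-6)
    )
    if separation and not firth:
        converged = False
    return beta, {
        "converged": converged,
        "n_iter": it,
        "loglik": ll,
        "objective": obj,
        "separation": separation,
    }


# ---------------------------------------------------------------------------
# Fitted model container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FittedModel:
    """A fitted logistic risk model with its frozen design recipe."""

    intercept: float
    coefficients: dict[str, float]
    design_recipe: Recipe
    selected: frozenset[str]
    converged: bool
    n_params: int
    estimator: str = "mle"
    loglik: float = math.nan
    diagnostic: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "design_recipe": [list(e) for e in self.design_recipe],
                "selected": sorted(self.selected),
                "converged": self.converged,
                "n_params": self.n_params,
                "estimator": self.estimator,
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "FittedModel":
        d = json.loads(text)
        recipe = tuple(
            tuple(tuple(x) if isinstance(x, list) else x for x in e)
            for e in d["design_recipe"]
        )
        return FittedModel(
            intercept=d["intercept"],
            coefficients=dict(d["coefficients"]),
            design_recipe=recipe,
            selected=frozenset(d["selected"]),
            converged=d["converged"],
            n_params=d["n_params"],
            estimator=d.get("estimator", "mle"),
        )


def _check_fittable(t: PatientTable) -> None:
    if not t.both_classes():
        raise ValidationError("both outcome classes must be present to fit")


def _rank_check(X: np.ndarray, names: list[str]) -> None:
    k = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # identify a minimal set of columns whose removal restores full rank
        bad = []
        keep = list(range(k))
        for j in range(k - 1, -1, -1):
            trial = [c for c in keep if c != j]
            if np.linalg.matrix_rank(X[:, trial]) == rank:
                bad.append(names[j - 1] if j > 0 else "(intercept)")
                keep = trial
                if len(keep) == rank:
                    break
        raise FitError(f"design matrix is rank deficient; collinear: {sorted(bad)}")


def _fit(
    t: PatientTable,
    spec: StrategySpec,
    recipe: Recipe,
    firth: bool,
) -> FittedModel:
    _check_fittable(t)
    X, names = build_design(t, recipe)
    Xd = np.hstack([np.ones((t.n, 1)), X])
    _rank_check(Xd, names)
    beta, info = newton_logistic(Xd, t.y.astype(float), firth=firth)
    diag = ""
    if not info["converged"]:
        diag = (
            "separation detected: MLE does not exist"
            if info["separation"] and not firth
            else f"no convergence in {info['n_iter']} iterations"
        )
    return FittedModel(
        intercept=float(beta[0]),
        coefficients={nm: float(b) for nm, b in zip(names, beta[1:])},
        design_recipe=recipe,
        selected=frozenset(e[1] for e in recipe),
        converged=info["converged"],
        n_params=len(names),
        estimator="firth" if firth else "mle",
        loglik=info["objective"],
        diagnostic=diag,
    )


def fit_mle_logistic(t: PatientTable, spec: StrategySpec) -> FittedModel:
    """Maximum-likelihood logistic regression on the prespecified predictors.

    Under (quasi-)separation the MLE does not exist; the returned model then
    carries ``converged=False`` and a diagnostic, never a silent result.
    """
    return _fit(t, spec, make_recipe(t, spec), firth=False)


def fit_firth_logistic(t: PatientTable, spec: StrategySpec) -> FittedModel:
    """Logistic regression with Firth's bias-reducing Jeffreys penalty.

    Estimates stay finite even under complete separation. No post-hoc
    intercept correction is applied (it would not affect rank-based
    discrimination or the calibration slope used downstream).
    """
    return _fit(t, spec, make_recipe(t, spec), firth=True)


def backward_eliminate(t: PatientTable, spec: StrategySpec) -> FittedModel:
    """Backward elimination with forced-in predictors.

    Repeatedly drops the non-forced predictor with the largest block
    likelihood-ratio p-value >= alpha, refitting after every removal, until
    all remaining non-forced predictors are significant at alpha.
    Multi-column predictors (dummy sets, spline pairs) are tested and removed
    as whole blocks; p-value ties are broken by schema order.
    """
    firth = spec.estimator == "firth"
    unknown = spec.forced - set(t.names)
    if unknown:
        raise ValidationError(f"forced predictors {sorted(unknown)} not in schema")
    selected = list(t.names)
    full_recipe = make_recipe(t, spec)
    by_name = {e[1]: e for e in full_recipe}
    model = _fit(t, spec, full_recipe, firth)
    while True:
        candidates = [nm for nm in selected if nm not in spec.forced]
        if not candidates:
            break
        worst_name, worst_p = None, -1.0
        reduced_fits: dict[str, FittedModel] = {}
        for nm in candidates:
            recipe = tuple(by_name[q] for q in selected if q != nm)
            sub = _fit(t, spec, recipe, firth)
            df = model.n_params - sub.n_params
            lr = max(2.0 * (model.loglik - sub.loglik), 0.0)
            pval = float(chi2.sf(lr, df))
            reduced_fits[nm] = sub
            if pval > worst_p:  # strict > keeps the earliest tied candidate
                worst_name, worst_p = nm, pval
        if worst_p >= spec.alpha:
            selected = [q for q in selected if q != worst_name]
            model = reduced_fits[worst_name]
        else:
            break
    return model


def apply_strategy(
    t: PatientTable, spec: StrategySpec, seed: int | Sequence[int] | None = None
) -> tuple[FittedModel, PatientTable]:
    """Run the complete strategy on ``t``; returns (model, data used).

    When the spec asks for single stochastic imputation and ``t`` has missing
    cells, the table is imputed first (the returned table is the completed
    one, so performance is evaluated on the data the model actually saw).
    """
    if t.has_missing():
        if spec.imputation == "none":
            raise ValidationError(
                "table has missing values but the strategy has no imputation step"
            )
        from .impute import fcs_impute_single  # local import avoids a cycle

        if seed is None:
            raise ValidationError("imputation requires a seed")
        t = fcs_impute_single(t, seed)
    if spec.selection == "backward":
        model = backward_eliminate(t, spec)
    elif spec.estimator == "firth":
        model = fit_firth_logistic(t, spec)
    else:
        model = fit_mle_logistic(t, spec)
    return model, t


def predict_lp(model: FittedModel, t: PatientTable) -> np.ndarray:
    """Linear predictor of a fitted model on (new) data.

    The stored recipe supplies knots and dummy codings; values beyond the
    training knots continue linearly by construction of the restricted basis.
    """
    X, names = build_design(t, model.design_recipe)
    coef = np.array([model.coefficients[nm] for nm in names])
    return model.intercept + X @ coef
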