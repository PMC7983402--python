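import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from accrue.core_data import PatientTable, PredictorMeta
from accrue.strategies import (
    FitError,
    FittedModel,
    StrategySpec,
    backward_eliminate,
    build_design,
    fit_firth_logistic,
    fit_mle_logistic,
    newton_logistic,
    predict_lp,
    rcs_basis,
    spline_knots,
)

SPEC = StrategySpec()


def _single(name="x", vtype="continuous", **kw):
    return (PredictorMeta(name, vtype, **kw),)


# ---------------------------------------------------------------------------
# restricted cubic spline basis
# ---------------------------------------------------------------------------

def test_rcs_zero_at_and_below_first_knot():
    x = np.array([-5.0, -1.0, 0.0])
    assert np.all(rcs_basis(x, (0, 1, 2)) == 0.0)


def test_rcs_exact_value_between_knots():
    # knots (0,1,2), x=1: [1 - 0 + 0] / 4
    assert rcs_basis(np.array([1.0]), (0, 1, 2))[0] == pytest.approx(0.25, abs=1e-15)


@pytest.mark.parametrize("region", [np.linspace(2.5, 9, 40), np.linspace(-9, -0.5, 40)])
def test_rcs_linear_beyond_boundary_knots(region):
    s = rcs_basis(region, (0.0, 1.0, 2.0))
    second_diff = np.diff(s, 2)
    assert np.all(np.abs(second_diff) < 1e-9)


def test_rcs_rejects_non_increasing_knots():
    with pytest.raises(ValueError):
        rcs_basis(np.array([1.0]), (0, 0, 2))


def test_spline_knots_degenerate_fall_back():
    assert spline_knots(np.zeros(100)) is None
    k = spline_knots(np.arange(100.0))
    assert k[0] < k[1] < k[2]


# ---------------------------------------------------------------------------
# maximum likelihood fitting
# ---------------------------------------------------------------------------

def test_intercept_only_mle_is_logit_of_mean():
    y = np.r_[np.ones(3), np.zeros(7)]
    t = PatientTable(y, {}, ())
    m = fit_mle_logistic(t, SPEC)
    assert m.converged and m.n_params == 0
    assert m.intercept == pytest.approx(np.log(0.3 / 0.7), abs=1e-6)


def test_single_binary_predictor_reproduces_log_odds_ratio():
    y = np.r_[np.ones(10), np.zeros(30), np.ones(20), np.zeros(20)]
    x = np.r_[np.zeros(40), np.ones(40)]
    t = PatientTable(y, {"x": x}, _single(vtype="binary"))
    m = fit_mle_logistic(t, SPEC)
    assert m.coefficients["x"] == pytest.approx(np.log(3), abs=1e-6)


def test_mle_matches_brute_force_likelihood_maximization(toy_table):
    """Newton solution == generic optimizer on the same log-likelihood."""
    m = fit_mle_logistic(toy_table, SPEC)
    X, names = build_design(toy_table, m.design_recipe)
    Xd = np.hstack([np.ones((toy_table.n, 1)), X])
    y = toy_table.y.astype(float)

    def negll(b):
        eta = Xd @ b
        return -(y @ eta - np.logaddexp(0, eta).sum())

    res = minimize(negll, np.zeros(Xd.shape[1]), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    got = np.r_[m.intercept, [m.coefficients[nm] for nm in names]]
    np.testing.assert_allclose(got, res.x, atol=1e-6)


def test_mle_matches_statsmodels(toy_table):
    sm = pytest.importorskip("statsmodels.api")
    m = fit_mle_logistic(toy_table, SPEC)
    X, names = build_design(toy_table, m.design_recipe)
    ref = sm.Logit(toy_table.y, sm.add_constant(X)).fit(disp=0)
    got = np.r_[m.intercept, [m.coefficients[nm] for nm in names]]
    np.testing.assert_allclose(got, ref.params, atol=1e-6)


def test_separation_is_flagged_not_silent():
    x = np.r_[-np.arange(1, 11.0), np.arange(1, 11.0)]
    y = (x > 0).astype(int)
    t = PatientTable(y, {"x": x}, _single())
    m = fit_mle_logistic(t, SPEC)
    assert not m.converged
    assert m.diagnostic


def test_rank_deficiency_names_collinear_columns():
    rng = np.random.default_rng(0)
    x = rng.normal(size=40)
    y = (rng.random(40) < expit(x)).astype(int)
    meta = (PredictorMeta("x", "continuous"), PredictorMeta("x2", "continuous"))
    t = PatientTable(y, {"x": x, "x2": 2 * x}, meta)
    with pytest.raises(FitError, match="collinear"):
        fit_mle_logistic(t, SPEC)


# ---------------------------------------------------------------------------
# Firth penalized fitting
# ---------------------------------------------------------------------------

def test_firth_intercept_only_closed_form():
    # penalized-likelihood intercept equals logit((k + 1/2) / (n + 1))
    y = np.r_[np.ones(3), np.zeros(7)]
    t = PatientTable(y, {}, ())
    m = fit_firth_logistic(t, SPEC)
    assert m.converged
    assert m.intercept == pytest.approx(np.log(3.5 / 7.5), abs=1e-6)


def test_firth_intercept_only_matches_grid_maximization():
    """Independent oracle: maximize ll + 0.5 log det I on a fine grid."""
    k, n = 3, 10
    grid = np.linspace(-3, 3, 120001)
    p = expit(grid)
    pen = k * grid - n * np.log1p(np.exp(grid)) + 0.5 * np.log(n * p * (1 - p))
    y = np.r_[np.ones(k), np.zeros(n - k)]
    m = fit_firth_logistic(PatientTable(y, {}, ()), SPEC)
    assert m.intercept == pytest.approx(grid[np.argmax(pen)], abs=1e-4)


def test_firth_finite_and_converged_under_separation():
    x = np.r_[-np.arange(1, 11.0), np.arange(1, 11.0)]
    y = (x > 0).astype(int)
    t = PatientTable(y, {"x": x}, _single())
    m = fit_firth_logistic(t, SPEC)
    assert m.converged
    assert np.isfinite(m.coefficients["x"])


def test_firth_shrinks_relative_to_mle_on_separated_data():
    x = np.r_[-np.arange(1, 11.0), np.arange(1, 11.0)]
    y = (x > 0).astype(int)
    t = PatientTable(y, {"x": x}, _single())
    mle = fit_mle_logistic(t, SPEC)
    fir = fit_firth_logistic(t, SPEC)
    assert abs(fir.coefficients["x"]) <= abs(mle.coefficients["x"])


def test_firth_and_mle_agree_at_large_n():
    rng = np.random.default_rng(12345)
    n = 50_000
    x = rng.normal(size=n)
    b = (rng.random(n) < 0.3).astype(float)
    y = (rng.random(n) < expit(-0.5 + 0.8 * x + 0.6 * b)).astype(int)
    meta = (PredictorMeta("x", "continuous"), PredictorMeta("b", "binary"))
    t = PatientTable(y, {"x": x, "b": b}, meta)
    m1 = fit_mle_logistic(t, SPEC)
    m2 = fit_firth_logistic(t, SPEC)
    for nm in ("x", "b"):
        assert m1.coefficients[nm] == pytest.approx(m2.coefficients[nm], abs=5e-3)


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------

def _selection_data(n=500, seed=7):
    rng = np.random.default_rng(seed)
    strong = rng.normal(size=n)
    null = rng.normal(size=n)
    age = rng.normal(size=n)
    y = (rng.random(n) < expit(-0.2 + 1.0 * strong + 0.3 * age)).astype(int)
    meta = (
        PredictorMeta("age", "continuous", forced=True),
        PredictorMeta("strong", "continuous"),
        PredictorMeta("null", "continuous"),
    )
    return PatientTable(y, {"age": age, "strong": strong, "null": null}, meta)


def test_all_forced_is_identical_to_plain_fit():
    t = _selection_data()
    spec = StrategySpec(selection="backward", forced=frozenset(t.names))
    m = backward_eliminate(t, spec)
    plain = fit_mle_logistic(t, StrategySpec())
    assert m.selected == frozenset(t.names)
    assert m.intercept == plain.intercept
    assert m.coefficients == plain.coefficients


def test_null_predictor_eliminated_strong_and_forced_retained():
    t = _selection_data()
    spec = StrategySpec(selection="backward", forced=frozenset({"age"}))
    m = backward_eliminate(t, spec)
    assert "null" not in m.selected
    assert {"age", "strong"} <= m.selected


def test_backward_matches_hand_rolled_elimination_loop():
    """Greedy largest-p-first removal, re-implemented independently."""
    from scipy.stats import chi2

    t = _selection_data(seed=11)
    spec = StrategySpec(selection="backward", forced=frozenset({"age"}))
    m = backward_eliminate(t, spec)

    def ll_of(names):
        cols = {nm: t.columns[nm] for nm in names}
        meta = tuple(mm for mm in t.meta if mm.name in names)
        sub = PatientTable(t.y, cols, meta)
        return fit_mle_logistic(sub, StrategySpec()).loglik

    selected = list(t.names)
    while True:
        cands = [nm for nm in selected if nm != "age"]
        if not cands:
            break
        full = ll_of(selected)
        pvals = [
            (nm, chi2.sf(2 * (full - ll_of([q for q in selected if q != nm])), 1))
            for nm in cands
        ]
        worst = max(pvals, key=lambda kv: kv[1])
        if worst[1] >= 0.05:
            selected.remove(worst[0])
        else:
            break
    assert m.selected == frozenset(selected)


def test_alpha_one_removes_nothing():
    t = _selection_data()
    spec = StrategySpec(selection="backward", alpha=1.0, forced=frozenset({"age"}))
    m = backward_eliminate(t, spec)
    assert m.selected == frozenset(t.names)


# ---------------------------------------------------------------------------
# linear predictor / design recipes
# ---------------------------------------------------------------------------

def test_lp_is_intercept_when_coefficients_zero(toy_table):
    m = fit_mle_logistic(toy_table, SPEC)
    zeroed = FittedModel(
        intercept=m.intercept,
        coefficients={k: 0.0 for k in m.coefficients},
        design_recipe=m.design_recipe,
        selected=m.selected,
        converged=True,
        n_params=m.n_params,
    )
    np.testing.assert_allclose(predict_lp(zeroed, toy_table), m.intercept)


def test_spline_model_extrapolates_linearly():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 10, 400)
    y = (rng.random(400) < expit(0.5 * x - 2)).astype(int)
    t = PatientTable(y, {"x": x}, _single(spline=True))
    spec = StrategySpec(use_splines=True)
    m = fit_mle_logistic(t, spec)
    assert m.n_params == 2  # x and its restricted cubic basis
    far = np.array([20.0, 30.0, 40.0])
    tnew = PatientTable(np.array([1, 0, 1]), {"x": far}, _single(spline=True))
    lp = predict_lp(m, tnew)
    assert np.all(np.isfinite(lp))
    slopes = np.diff(lp) / np.diff(far)
    assert slopes[0] == pytest.approx(slopes[1], rel=1e-9)


def test_unseen_categorical_level_is_an_error():
    meta = (PredictorMeta("g", "categorical", levels=("a", "b", "c")),)
    rng = np.random.default_rng(5)
    g = rng.integers(0, 3, 60).astype(float)
    y = (rng.random(60) < expit(0.8 * (g == 2) - 0.2)).astype(int)
    t = PatientTable(y, {"g": g}, meta)
    m = fit_mle_logistic(t, SPEC)
    meta4 = (PredictorMeta("g", "categorical", levels=("a", "b", "c", "d")),)
    tnew = PatientTable(np.array([0, 1]), {"g": np.array([0.0, 3.0])}, meta4)
    with pytest.raises(Exception, match="unseen"):
        predict_lp(m, tnew)


def test_fit_is_deterministic(toy_table):
    m1 = fit_mle_logistic(toy_table, SPEC)
    m2 = fit_mle_logistic(toy_table, SPEC)
    assert m1.intercept == m2.intercept
    assert m1.coefficients == m2.coefficients


def test_spline_expansion_adds_one_parameter_per_flagged_predictor(ovarian_cfg, cad_cfg):
    from accrue.synthetic import generate_population
    from accrue.impute import fcs_impute_single

    ov = generate_population(ovarian_cfg, n=800, seed=1)
    assert fit_mle_logistic(ov, StrategySpec()).n_params == 7
    assert fit_mle_logistic(ov, StrategySpec(use_splines=True)).n_params == 10
    cad = fcs_impute_single(generate_population(cad_cfg, n=800, seed=1), seed=2)
    assert fit_mle_logistic(cad, StrategySpec()).n_params == 12
    assert fit_mle_logistic(cad, StrategySpec(use_splines=True)).n_params == 16


def test_model_json_round_trip(toy_table):
    m = fit_mle_logistic(toy_table, SPEC)
    m2 = FittedModel.from_json(m.to_json())
    assert m2.coefficients == m.coefficients
    np.testing.assert_allclose(predict_lp(m2, toy_table), predict_lp(m, toy_table))
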