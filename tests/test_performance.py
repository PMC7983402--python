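import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from accrue.performance import (
    PerfEstimate,
    UndefinedMetricError,
    c_statistic,
    calibration_slope,
    enhanced_bootstrap,
)
from accrue.strategies import StrategySpec, apply_strategy, fit_mle_logistic, predict_lp
from conftest import make_toy_table

SPEC = StrategySpec()


# ---------------------------------------------------------------------------
# c-statistic
# ---------------------------------------------------------------------------

def brute_force_auc(scores, y):
    """Pairwise enumeration with ties counted one half."""
    ev = [s for s, yi in zip(scores, y) if yi == 1]
    ne = [s for s, yi in zip(scores, y) if yi == 0]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a, b in itertools.product(ev, ne))
    return wins / (len(ev) * len(ne))


def test_c_statistic_worked_pair_enumeration():
    scores = np.array([0.9, 0.4, 0.5, 0.2, 0.4])
    y = np.array([1, 1, 0, 0, 0])
    assert c_statistic(scores, y) == pytest.approx(4.5 / 6)
    assert c_statistic(scores, y) == pytest.approx(brute_force_auc(scores, y))


def test_c_statistic_boundary_cases():
    assert c_statistic(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1])) == 1.0
    assert c_statistic(np.ones(6), np.array([0, 1, 0, 1, 0, 1])) == 0.5
    with pytest.raises(UndefinedMetricError):
        c_statistic(np.arange(4.0), np.zeros(4))


@given(
    st.lists(st.integers(0, 5), min_size=2, max_size=20),
    st.data(),
)
def test_c_statistic_equals_enumeration_on_small_inputs(score_ints, data):
    n = len(score_ints)
    y = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    if sum(y) in (0, n):
        y[0] = 1 - y[0]
    scores = np.array(score_ints, dtype=float)  # heavy ties on purpose
    assert c_statistic(scores, np.array(y)) == pytest.approx(
        brute_force_auc(scores, y)
    )


def test_c_statistic_invariant_under_monotone_transform():
    rng = np.random.default_rng(1)
    s = rng.normal(size=50)
    y = (rng.random(50) < 0.4).astype(int)
    assert c_statistic(np.exp(s), y) == pytest.approx(c_statistic(s, y))


# ---------------------------------------------------------------------------
# calibration slope
# ---------------------------------------------------------------------------

def test_apparent_slope_of_mle_fit_is_one(toy_table):
    m = fit_mle_logistic(toy_table, SPEC)
    lp = predict_lp(m, toy_table)
    assert calibration_slope(lp, toy_table.y) == pytest.approx(1.0, abs=1e-6)


def test_slope_scale_equivariance(toy_table):
    m = fit_mle_logistic(toy_table, SPEC)
    lp = predict_lp(m, toy_table)
    s1 = calibration_slope(lp, toy_table.y)
    s2 = calibration_slope(lp / 2.0, toy_table.y)
    assert s2 == pytest.approx(2 * s1, rel=1e-6)


def test_zero_variance_lp_is_undefined():
    with pytest.raises(UndefinedMetricError):
        calibration_slope(np.zeros(10), np.r_[np.ones(4), np.zeros(6)])


def test_overfit_model_shows_slope_below_one_on_holdout(ovarian_cfg):
    """Small-n models give too-extreme risks: holdout slope < 1 on average."""
    from accrue.synthetic import generate_population

    pop = generate_population(ovarian_cfg, n=6000, seed=31)
    slopes = []
    for rep in range(12):
        rng = np.random.default_rng(rep)
        perm = rng.permutation(pop.n)
        dev, hold = pop.take(perm[:100]), pop.take(perm[100:3000])
        model, _ = apply_strategy(dev, SPEC)
        if not model.converged:
            continue
        slopes.append(calibration_slope(predict_lp(model, hold), hold.y))
    assert np.mean(slopes) < 1.0


# ---------------------------------------------------------------------------
# enhanced bootstrap
# ---------------------------------------------------------------------------

def test_enhanced_bootstrap_equals_hand_rolled_loop(toy_table):
    """B=3 fixed-seed run must match an independently coded a-g loop."""
    B, seed = 3, 123
    got = enhanced_bootstrap(toy_table, SPEC, B=B, seed=seed)

    model_d, _ = apply_strategy(toy_table, SPEC)
    lp_d = predict_lp(model_d, toy_table)
    auc_app = c_statistic(lp_d, toy_table.y)
    slope_app = calibration_slope(lp_d, toy_table.y)
    opt_auc, opt_slope = [], []
    for b in range(1, B + 1):
        rng = np.random.default_rng([seed, b])
        idx = rng.integers(0, toy_table.n, toy_table.n)
        boot = toy_table.take(idx)
        m_b, _ = apply_strategy(boot, SPEC)
        lp_b = predict_lp(m_b, boot)
        lp_o = predict_lp(m_b, toy_table)
        opt_auc.append(c_statistic(lp_b, boot.y) - c_statistic(lp_o, toy_table.y))
        opt_slope.append(
            calibration_slope(lp_b, boot.y) - calibration_slope(lp_o, toy_table.y)
        )
    assert got.B_used == B and got.failed_replicates == 0
    assert got.auc_apparent == auc_app
    assert got.slope_apparent == slope_app
    assert got.auc_optimism == pytest.approx(np.mean(opt_auc), abs=1e-15)
    assert got.slope_corrected == pytest.approx(slope_app - np.mean(opt_slope), abs=1e-15)


def test_data_independent_model_has_no_optimism_on_average():
    """A strategy that ignores the data is not optimistic (in expectation).

    With fixed coefficients the per-replicate difference PM_B - PM_O is pure
    resampling noise around zero, so the averaged optimism vanishes and the
    corrected estimates coincide with the apparent ones up to that noise.
    """
    t = make_toy_table(n=200, seed=9)
    frozen, _ = apply_strategy(t, SPEC)

    def fixed_fit(tbl, key):
        return frozen, tbl

    got = enhanced_bootstrap(t, SPEC, B=200, seed=5, fit_fn=fixed_fit)
    assert got.auc_optimism == pytest.approx(0.0, abs=0.01)
    assert got.slope_apparent - got.slope_corrected == pytest.approx(0.0, abs=0.05)


def test_bootstrap_is_deterministic(toy_table):
    a = enhanced_bootstrap(toy_table, SPEC, B=8, seed=99)
    b = enhanced_bootstrap(toy_table, SPEC, B=8, seed=99)
    assert a == b


def test_optimism_identity_and_bookkeeping(toy_table):
    got = enhanced_bootstrap(toy_table, SPEC, B=5, seed=7)
    assert got.auc_optimism == pytest.approx(got.auc_apparent - got.auc_corrected)
    assert got.B_used == got.B_requested - got.failed_replicates
    with pytest.raises(ValueError):
        PerfEstimate(10, 3, 0.8, 0.7, 0.1, 1.0, 0.9, 5, 3, 1)


def test_stratified_resampling_preserves_event_count():
    """With within-class resampling no replicate can lose a class, so a
    tiny, very unbalanced table still yields usable replicates."""
    t = make_toy_table(n=40, seed=33)
    got = enhanced_bootstrap(t, SPEC, B=20, seed=3, stratified=True)
    plain = enhanced_bootstrap(t, SPEC, B=20, seed=3)
    assert got.B_used >= plain.B_used
    assert got != plain  # different resampling scheme, different estimate


def test_mean_optimism_shrinks_with_sample_size(ovarian_cfg):
    """Optimism disappears as n grows (mean over many seeds)."""
    from accrue.synthetic import generate_population

    pop = generate_population(ovarian_cfg, n=120_000, seed=8)
    opt = {100: [], 2000: []}
    for s in range(50):
        rng = np.random.default_rng(s)
        for n in opt:
            idx = rng.choice(pop.n, n, replace=False)
            try:
                perf = enhanced_bootstrap(pop.take(idx), SPEC, B=20, seed=s)
            except Exception:
                continue
            opt[n].append(perf.auc_optimism)
    assert np.mean(opt[2000]) < np.mean(opt[100])
    assert np.mean(opt[100]) > 0  # apparent >= corrected on average for MLE
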