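# Methods

## The problem

A clinical risk prediction model (a logistic regression estimating, say, the
probability that an ovarian mass is malignant) needs enough development data
that its risk estimates generalize. Fixed a priori sample-size rules — 10
events per candidate parameter (EPP), or the Cox-Snell-R²-based minimum
sample-size criteria — fix `n` before any data exist and cannot react to the
modeling context actually encountered. `accrue` implements the alternative:
an *adaptive* procedure that monitors internally validated performance while
patients accrue and stops recruitment when prespecified targets are met.

## The adaptive procedure

1. Compute an initial estimate N₀ from a fixed calculator (`accrue.fixed_size`).
   N₀ is advisory: it is reported but does not constrain stopping (an option
   exists to suppress stopping before N₀, off by default).
2. Recruit `n_start` patients (default 100) and fit the prespecified strategy.
3. Internally validate with the enhanced bootstrap (below) at `B` replicates
   (default 200).
4. Recruit `n_add` more patients (default 50) and repeat.
5. Stop when a stopping rule is satisfied: bootstrap-corrected calibration
   slope ≥ 0.9 **and** AUC optimism ≤ 0.02 (rule 1) or ≤ 0.01 (rule 2), on
   two consecutive assessments. Thresholds are inclusive. The final model is
   the fit at the assessment that *completes* the consecutive requirement.

An assessment whose fit or metric computation fails is recorded with status
`undefined`; it never counts toward the consecutive requirement and resets
the run (a conservative choice: stopping should not rest on unverifiable
performance). The engine can also run in "exhaust" mode, continuing to the
cap `n_max` even after rules fire, which yields fixed-length learning curves
for study purposes.

## Enhanced bootstrap internal validation

For development data D with fitted model M_D and apparent performance PM_D,
each replicate: resample |D| rows with replacement; rerun the *complete*
strategy (spline-knot re-estimation, variable re-selection, re-imputation if
configured) to get M_B; record PM_B (M_B on the resample) and PM_O (M_B on
D). Optimism is the mean of PM_B − PM_O over replicates; corrected
performance is PM_D minus optimism, computed for the c-statistic and the
calibration slope. The apparent slope is *refit*, not assumed to be 1 — it
is exactly 1 for maximum-likelihood fits (score equations) but not for
penalized ones. Replicates that fail (single-class resample, non-convergence,
undefined metric) are dropped and counted; using fewer than half the
requested replicates flags the estimate. Replicate `b` draws from an RNG
keyed by `(seed, b)`, so estimates are independent of execution order.

Note one subtlety: for a *data-independent* model, PM_B (evaluated on the
resample) and PM_O (evaluated on D) still differ per replicate by resampling
noise; optimism is zero only in expectation. The test suite checks the
expectation, not per-replicate equality.

## Performance measures

* **c-statistic / AUC** — Mann-Whitney form via average ranks; ties count ½.
* **Calibration slope** — slope of an ML logistic refit of `y` on the linear
  predictor, free intercept. Slope < 1: risks too extreme (overfitting).
  The calibration intercept is computed but not used by the stopping rules;
  it carries little information at internal validation.

## Modeling strategies

All strategies are pure functions of (data, spec): identical inputs give
bit-identical models.

* **Basic** — ML logistic regression on the prespecified predictors, linear
  continuous effects.
* **Restricted cubic splines** — 3 knots at the 0.10/0.50/0.90 empirical
  quantiles of the current development data (the convention of the standard
  regression-modeling toolkit; locations are otherwise a free choice), one
  extra parameter per spline-flagged continuous predictor. Knots are stored
  in the model, so bootstrap models carry their own knots and new data are
  expanded with the training knots (linear continuation beyond them). If the
  quantiles tie, the predictor falls back to a linear term.
* **Firth's correction** — Jeffreys-penalized likelihood ℓ(β) + ½·log det I(β),
  fitted by Newton iteration on the hat-value-modified score
  Σᵢ(yᵢ − πᵢ + hᵢ(½ − πᵢ))xᵢ with step-halving; finite estimates under
  separation. No post-hoc intercept correction is applied — it would not
  change rank-based discrimination or the calibration slope (a real
  deployment would need one).
* **Backward elimination** — greedy removal of the non-forced predictor with
  the largest block likelihood-ratio p-value ≥ α (default 0.05), refitting
  after each removal; ties broken by schema order. Blocks (dummy sets,
  spline pairs) are tested and removed whole. Wald-vs-LR is a genuinely open
  choice; LR on blocks treats multi-column predictors coherently. Forced
  predictors (e.g. age; age and sex for the CAD-like scenario) are never
  removed, which also precludes empty models.

### Numerical choices

Convergence: relative change in the (penalized) log-likelihood < 1e-8 *and*
final Newton step < 1e-7 in every coordinate (objective flatness alone can
leave ~1e-4 parameter error); max 100 iterations (ML) / 250 (Firth).
Separation is detected by perfect prediction at 1e-6 tolerance and surfaces
as `converged=False` with a diagnostic for ML fits, never silently. Rank
deficiency raises an error naming the collinear columns.

## Fixed sample-size calculators

`epp_sample_size(epp, p, phi) = ceil(epp·p/phi)`. Fractional patients round
*up* (the printed convention in the source arithmetic). The R²-based
criteria: n₁ = p/((S−1)·ln(1 − R²/S)) with shrinkage target S = 0.9;
n₂ re-applies the same formula with S replaced by R²/(R² + δ·R²_max(φ)),
δ = 0.05, where R²_max(φ) = 1 − (φ^φ(1−φ)^(1−φ))²; n₃ = (1.96/margin)²·φ(1−φ)
with margin 0.05. The anticipated R²_CS is a required input with no default:
the published totals for the two case studies (314 and 669) depend on
anticipated values that are not in the public record, so they are treated as
user inputs, not package constants. `round_to_batch` rounds up to the next
accrual-batch multiple.

## Synthetic scenarios

The two packaged scenarios emulate the published case-mix (marginal means,
ranges, prevalences, missingness rates), **not** the real joint
distributions, which are not publicly deposited. Predictors are drawn via a
Gaussian copula; marginal shapes are modeling choices: log-normal diameters
(right-skewed, mean 82 mm over an 8–760 mm range), truncated-normal age, a
zero-inflated Beta fraction for the solid-component share of the lesion
diameter (enforcing solid ≤ lesion structurally), an integer papillation
score 0–4. The papillation count enters as a single numeric score because
the stated parameter count (7 parameters for 7 predictors) rules out dummy
coding; three-level smoking is reference-coded into two dummies, giving the
stated 12 parameters for 11 CAD predictors.

Outcomes follow y ~ Bernoulli(expit(α + s·z(x)ᵀβ)) with β fixed signs/ratios
and (α, s) calibrated by root-finding on a fixed-seed draw of 10⁵ patients:
α so the mean event probability equals the target prevalence (0.33 / 0.44),
s so the population c-statistic of the true linear predictor equals the
target AUC (0.90 / 0.70), computed in closed form from pairwise concordance
weighted by event probabilities. Calibration is deterministic and cached on
the config; targets verify out-of-sample to ±0.01.

Missingness in the CAD-like scenario is MAR driven by age (logistic in
standardized age, slope 0.5; the intercept is root-found per column so the
marginal rate matches the published one: HDL 6.4%, LDL 6.3%, log-fibrinogen
4.1%, CRP 2%, smoking 13%). MCAR is available. What passing tests on these
scenarios do *not* show: behavior under real-data features such as
measurement error, nonlinear true effects, interactions, informative
missingness, or the exact real-data correlation structure.

## Imputation

Single stochastic FCS: 10 chained cycles; each incomplete column is
regressed on all other predictors plus the outcome (OLS with normal noise
for continuous, clipped to the observed range; Firth-stabilized logistic
draw for binary; multinomial logistic draw for categorical); one stochastic
draw fills each missing cell; observed cells are untouched. Columns > 95%
missing are an error.

MI-in-bootstrap embeds m imputations inside each replicate: apparent
performance averages over m completed versions of the development data; each
replicate is re-imputed m times and PM_B/PM_O are averaged across
imputations *before* the optimism difference. Model-j of the replicate is
evaluated against completed development version j. The exact combination
order (average performances vs pool models) is an open design point; the
implemented choice averages performances, which is all the stopping rules
need (no pooled inference is attempted). On complete data the routine
reduces exactly to the plain enhanced bootstrap.

## Resampling-study harness

Each repetition permutes the population uniformly, feeds the first `n_max`
rows to the adaptive engine (sampling without replacement, as in the source
design, which may understate real prospective variability), and evaluates
every interim model on the suffix — patients never used for development in
that repetition — as a holdout check. Stop sizes, EPP at stop, and corrected
AUC/slope at stop are summarized by median and IQR using linear
interpolation between order statistics (the convention is fixed so IQRs
reproduce bit-exactly); average learning and holdout curves are pointwise
means. Repetitions are keyed by (root seed, repetition index) and are
schedule-independent.

### Problem sizes used

The published design (500 repetitions, B=200, cap 3000) is configurable but
large; the package defaults and the bundled acceptance checks use a desk
scale chosen to keep qualitative conclusions stable: 10 repetitions, B=100,
cap 1500, populations of 5914 / 4888. The CAD-like study imputes its
population once up front with single stochastic FCS and then runs on
complete data — the same illustrative simplification used in the source
design — while imputation-inside-bootstrap is exercised separately at small
scale.

## Known limitations

* No formal sequential error control: the procedure is monitoring, not a
  hypothesis test; stopping rules are heuristic targets.
* Binary outcomes only; no survival or multinomial variants.
* Firth model evaluation, backward-elimination p-values and FCS conditional
  models are the standard textbook forms; exotic data (heavy separation in
  tiny strata, degenerate categorical cells) surface as flagged failures
  rather than being repaired.
* The scaled-down study inherits Monte-Carlo noise: median stop sizes at 10
  repetitions carry an IQR-wide uncertainty and are compared only
  qualitatively (ordering, trends), never to published point values.
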