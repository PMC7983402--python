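# accrue

**Adaptive sample size determination for clinical risk prediction models.**

Fixed sample-size rules for developing a binary-outcome prediction model —
10 events per candidate parameter (EPP), or the Cox-Snell-R²-based minimum
sample-size criteria — commit to an `n` before any data exist. `accrue`
implements the adaptive alternative for studies where outcomes are known
quickly: recruit a starting batch, internally validate the prespecified
model with the enhanced bootstrap, keep recruiting in batches, and **stop
when optimism-corrected performance meets prespecified targets**:

> calibration slope ≥ 0.9 **and** AUC optimism ≤ 0.02 (rule 1) or ≤ 0.01
> (rule 2), on two consecutive assessments.

Here the calibration slope is the coefficient of a logistic refit of the
outcome on the model's linear predictor (slope < 1: risks too extreme,
i.e. overfitting), AUC is the c-statistic, and optimism is estimated by
Harrell's enhanced bootstrap: refit the *complete* modeling strategy on each
resample, average PM_B − PM_O over replicates, and subtract from the
apparent performance.

The package is aimed at biostatisticians planning or monitoring prediction
model development. It bundles:

* `accrue.fixed_size` — a priori calculators: EPP rule, Cox-Snell-R²-based
  minimum-n criteria, accrual-batch rounding;
* `accrue.strategies` — four prespecified logistic strategies: plain ML,
  restricted cubic splines (3 knots), Firth's penalized likelihood,
  backward elimination with forced variables;
* `accrue.performance` — c-statistic, calibration slope, enhanced bootstrap;
* `accrue.adaptive` — the accrual engine and stopping rules, producing
  learning curves;
* `accrue.synthetic` — calibrated synthetic case studies (an ovarian-tumour
  -like scenario: 7 predictors, 33% events, AUC ≈ 0.9; a coronary-artery-
  disease-like scenario: 11 predictors, 44% events, AUC ≈ 0.7, with
  realistic missingness) plus FCS imputation, single and MI-in-bootstrap;
* `accrue.study` — a resampling harness: repeated without-replacement
  accrual from a fixed population, holdout evaluation, median/IQR summaries
  and average learning curves.

## Worked example

Internally validate the basic 7-parameter strategy on 200 synthetic
patients (`examples/03_internal_validation.py`):

```text
n=200, events=50, replicates used 190/200
AUC   apparent 0.935 -> corrected 0.920 (optimism 0.015)
slope apparent 1.000 -> corrected 0.836
corrected slope < 0.9 means this sample is too small to stop recruiting
```

At 200 patients the apparent AUC overstates performance by 0.015 and the
corrected calibration slope (0.836) says the risk estimates are ~16% too
extreme — the stopping rule keeps recruitment open. Ten of 200 bootstrap
refits failed (separated resamples) and are counted, not hidden.

The a priori calculators (`examples/01_fixed_sample_size.py`):

```text
10 EPP rule: n = 215 (ceil of 10*7/0.3265)
R2-based criteria: shrinkage 86.3, optimism 136.3, margin 337.9
  minimum n = 338, implied EPP = 15.8
  batch-rounded (50s): 350
```

The other examples generate populations (`02`), run one adaptive accrual to
its stopping points (`04`), and run the scaled resampling study with
holdout comparison (`05`). A thin CLI mirrors these: `accrue simulate-data`,
`accrue fixed-size`, `accrue run-adaptive`, `accrue run-study`,
`accrue plot`.

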