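"""One adaptive accrual run: grow the sample until the stopping rules fire.

Streams a synthetic ovarian-like population in recruitment order, assesses
bootstrap-corrected performance every 50 patients from n=100, and reports
where each stopping rule is satisfied (slope >= 0.9 with AUC optimism
<= 0.02 for rule 1 / <= 0.01 for rule 2, twice in a row).
"""

from accrue import AccrualConfig, StoppingRule, StrategySpec, run_adaptive
from accrue.synthetic import generate_population, ovarian_like

stream = generate_population(ovarian_like(), n=1500, seed=11)
acc = AccrualConfig(n_start=100, n_add=50, n_max=1500, B=200, seed=3)
rules = (StoppingRule("rule1", 0.9, 0.02, 2), StoppingRule("rule2", 0.9, 0.01, 2))

curve = run_adaptive(stream, StrategySpec(), acc, rules)

print(curve.to_frame()[["n", "auc_corrected", "auc_optimism", "slope_corrected",
                        "status_rule1", "status_rule2"]].to_string(index=False))
print(f"\nstop sizes: {curve.stop_n}")
print("the final model for each rule is the fit at the assessment that")
print("completed the two-consecutive requirement")
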