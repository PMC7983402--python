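"""Internally validate one model with the enhanced bootstrap.

Fits the basic logistic strategy on a small development set and reports
apparent vs bootstrap-corrected AUC and calibration slope. At n=200 with 7
parameters the corrected slope falls clearly below 1: the apparent fit is
optimistic and the estimated risks are too extreme.
"""

from accrue import StrategySpec, enhanced_bootstrap
from accrue.synthetic import generate_population, ovarian_like

dev = generate_population(ovarian_like(), n=200, seed=7)
perf = enhanced_bootstrap(dev, StrategySpec(), B=200, seed=1)

print(f"n={perf.n}, events={perf.events}, replicates used {perf.B_used}/{perf.B_requested}")
print(f"AUC   apparent {perf.auc_apparent:.3f} -> corrected {perf.auc_corrected:.3f} "
      f"(optimism {perf.auc_optimism:.3f})")
print(f"slope apparent {perf.slope_apparent:.3f} -> corrected {perf.slope_corrected:.3f}")
print("corrected slope < 0.9 means this sample is too small to stop recruiting")
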