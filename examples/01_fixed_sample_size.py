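"""A priori fixed sample-size calculations for a planned prediction model.

Computes the events-per-parameter rule of thumb and the Cox-Snell-R2-based
minimum sample size for a 7-parameter model at 33% outcome prevalence, and
rounds the result up to the accrual batch.
"""

from accrue import RileyInputs, epp_sample_size, riley_min_n, round_to_batch

p, phi = 7, 1931 / 5914

n_epp = epp_sample_size(10, p, phi)
print(f"10 EPP rule: n = {n_epp} (ceil of 10*{p}/{phi:.4f})")

res = riley_min_n(RileyInputs(p=p, phi=phi, r2cs=0.5, shrinkage_target=0.9))
n1, n2, n3 = res.n_by_criterion
print(f"R2-based criteria: shrinkage {n1:.1f}, optimism {n2:.1f}, margin {n3:.1f}")
print(f"  minimum n = {res.n_total}, implied EPP = {res.epp_implied:.1f}")
print(f"  batch-rounded (50s): {round_to_batch(res.n_total, 50)}")

# The EPP rule ignores predictive strength entirely; the R2-based criteria
# grow as the anticipated signal (r2cs) weakens:
for r2 in (0.1, 0.2, 0.5):
    n = riley_min_n(RileyInputs(p=p, phi=phi, r2cs=r2)).n_total
    print(f"  anticipated R2_CS={r2}: minimum n = {n}")
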