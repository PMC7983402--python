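"""A priori fixed sample-size calculators for binary risk-model development.

Two families are provided as initial estimates (N0) for the adaptive
procedure: the events-per-parameter (EPP) rule of thumb, and the minimum
sample-size criteria of Riley et al. based on the anticipated Cox-Snell R2,
a global shrinkage target and the precision of the estimated event fraction.
Fractional patient counts always round up, and batch rounding rounds up to
the next multiple of the accrual batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "RileyInputs",
    "RileyResult",
    "epp_sample_size",
    "riley_min_n",
    "round_to_batch",
    "r2cs_max",
]


def epp_sample_size(epp: float, p: int, phi: float) -> int:
    """Sample size needed for ``epp`` events per candidate parameter.

    ``ceil(epp * p / phi)`` where ``p`` counts candidate regression
    coefficients (excluding the intercept) and ``phi`` is the anticipated
    event fraction.
    """
    if epp <= 0:
        raise ValueError("epp must be positive")
    if p < 1:
        raise ValueError("p must be >= 1")
    if not (0 < phi < 1):
        raise ValueError("event fraction must be in (0, 1)")
    return math.ceil(epp * p / phi)


def r2cs_max(phi: float) -> float:
    """Maximum attainable Cox-Snell R2 at event fraction ``phi``."""
    if not (0 < phi < 1):
        raise ValueError("event fraction must be in (0, 1)")
    ll0 = phi * math.log(phi) + (1 - phi) * math.log(1 - phi)
    return 1 - math.exp(2 * ll0)


@dataclass(frozen=True)
class RileyInputs:
    """Inputs to the Cox-Snell-R2-based minimum sample-size criteria.

    ``r2cs`` is the anticipated Cox-Snell R2 of the model (must lie below the
    prevalence-dependent maximum); ``shrinkage_target`` is the desired global
    shrinkage factor S; ``r2_optimism_delta`` bounds the absolute optimism in
    apparent R2 as a fraction of the maximum R2; ``risk_margin`` is the
    half-width of the 95% margin on the estimated event fraction.
    """

    p: int
    phi: float
    r2cs: float
    shrinkage_target: float = 0.9
    r2_optimism_delta: float = 0.05
    risk_margin: float = 0.05

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if not (0 < self.phi < 1):
            raise ValueError("phi must be in (0, 1)")
        if not (0 < self.shrinkage_target < 1):
            raise ValueError("shrinkage target must be in (0, 1)")
        rmax = r2cs_max(self.phi)
        if not (0 < self.r2cs < rmax):
            raise ValueError(
                f"r2cs must be in (0, {rmax:.4f}) at phi={self.phi:.3f}"
            )


@dataclass(frozen=True)
class RileyResult:
    n_total: int
    n_by_criterion: tuple[float, float, float]
    epp_implied: float


def _n_shrinkage(p: int, r2cs: float, s: float) -> float:
    # n = p / ((S-1) ln(1 - R2/S))
    return p / ((s - 1) * math.log(1 - r2cs / s))


def riley_min_n(inputs: RileyInputs) -> RileyResult:
    """Minimum development sample size from the three fixed criteria.

    Criterion 1 targets expected shrinkage >= the shrinkage target;
    criterion 2 bounds the optimism in apparent Cox-Snell R2 (by re-applying
    the shrinkage formula with S replaced by R2/(R2 + delta * R2_max));
    criterion 3 requires the event fraction to be estimated within
    ``risk_margin`` at 95% confidence. The total is the ceiling of the
    largest criterion.
    """
    p, phi, r2 = inputs.p, inputs.phi, inputs.r2cs
    n1 = _n_shrinkage(p, r2, inputs.shrinkage_target)
    s2 = r2 / (r2 + inputs.r2_optimism_delta * r2cs_max(phi))
    n2 = _n_shrinkage(p, r2, s2)
    n3 = (1.96 / inputs.risk_margin) ** 2 * phi * (1 - phi)
    n_total = math.ceil(max(n1, n2, n3))
    return RileyResult(
        n_total=n_total,
        n_by_criterion=(n1, n2, n3),
        epp_implied=n_total * phi / p,
    )


def round_to_batch(n: int, batch: int) -> int:
    """Smallest multiple of ``batch`` that is >= ``n``."""
    if batch < 1:
        raise ValueError("batch must be >= 1")
    return math.ceil(n / batch) * batch
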