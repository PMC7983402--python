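import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from accrue.core_data import PatientTable, PredictorMeta
from accrue.synthetic import cad_like, calibrate_scenario, ovarian_like

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ovarian_cfg():
    cfg = ovarian_like()
    calibrate_scenario(cfg)
    return cfg


@pytest.fixture(scope="session")
def cad_cfg():
    cfg = cad_like()
    calibrate_scenario(cfg)
    return cfg


TOY_META = (
    PredictorMeta("x1", "continuous"),
    PredictorMeta("x2", "continuous"),
    PredictorMeta("b1", "binary"),
)


def make_toy_table(n: int = 30, seed: int = 42) -> PatientTable:
    """Small complete table with real signal, for bootstrap oracles."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0, 1, n)
    x2 = rng.normal(0, 1, n)
    b1 = (rng.random(n) < 0.4).astype(float)
    lp = -0.3 + 1.2 * x1 - 0.6 * x2 + 0.8 * b1
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    if y.sum() in (0, n):  # pragma: no cover - seed chosen to avoid this
        y[0], y[-1] = 0, 1
    return PatientTable(y, {"x1": x1, "x2": x2, "b1": b1}, TOY_META)


@pytest.fixture
def toy_table() -> PatientTable:
    return make_toy_table()
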