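import numpy as np
import pytest

from mhspc_cea import (
    DeathProb,
    KMCurve,
    LifeTable,
    MarkovCEModel,
    ModelConfig,
    default_scenario,
)


@pytest.fixture(scope="session")
def flat_life_table() -> LifeTable:
    """Zero background mortality until the closing row at age 100."""
    ages = np.arange(60, 101)
    q = np.zeros(ages.size)
    q[-1] = 1.0
    return LifeTable(ages, q)


@pytest.fixture(scope="session")
def gompertz_life_table() -> LifeTable:
    ages = np.arange(60, 101)
    q = np.minimum(1.0, 0.011 * 1.09 ** (ages - 60.0))
    q[-1] = 1.0
    return LifeTable(ages, q)


@pytest.fixture(scope="session")
def short_config() -> ModelConfig:
    return ModelConfig(horizon_cycles=120)


@pytest.fixture(scope="session")
def exp_curve() -> KMCurve:
    """Noise-free digitization of S(t) = exp(-0.05 t) on months 0..60."""
    t = np.arange(0.0, 61.0)
    return KMCurve("PFS", "exp", t, np.exp(-0.05 * t))


@pytest.fixture(scope="session")
def fitted_results():
    """One fitted base-case pipeline on the default synthetic scenario,
    shared across tests (read-only)."""
    model = MarkovCEModel.from_scenario(default_scenario(seed=101))
    return model.fit()
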