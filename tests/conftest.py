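import numpy as np
import pytest

from hdmedsurv import SimulationConfig, SurvivalDataset, calibrate_c0, simulate_dataset


@pytest.fixture(scope="session")
def sim_small():
    """One moderate replicate of the default generative model (n=200, p=50)."""
    cfg = SimulationConfig(n=200, p=50, seed=42, censor_target=0.15)
    c0 = calibrate_c0(cfg, 0.15)
    data, truth = simulate_dataset(cfg, replicate=0, c0=c0)
    return cfg, data, truth


@pytest.fixture(scope="session")
def sim_mid():
    """A larger replicate for recovery checks (n=800, p=100)."""
    cfg = SimulationConfig(n=800, p=100, seed=7, censor_target=0.15)
    c0 = calibrate_c0(cfg, 0.15)
    data, truth = simulate_dataset(cfg, replicate=0, c0=c0)
    return cfg, data, truth


@pytest.fixture()
def toy_data():
    """Hand-sized dataset with distinct times and a couple of mediators."""
    rng = np.random.default_rng(123)
    n = 12
    time = np.arange(1, n + 1, dtype=float)
    event = np.ones(n)
    event[[3, 8]] = 0.0
    exposure = (np.arange(n) % 2).astype(float)
    covariates = np.column_stack([rng.uniform(size=n)])
    mediators = rng.normal(size=(n, 3))
    return SurvivalDataset(time=time, event=event, exposure=exposure,
                           covariates=covariates, mediators=mediators)
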