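import numpy as np
import pandas as pd
import pytest

from enviromort.synthetic import (
    ScenarioConfig,
    generate_daily_exposures,
    generate_weekly_mortality,
)


@pytest.fixture(scope="session")
def scenario26() -> ScenarioConfig:
    return ScenarioConfig(n_years=26, seed=1)


@pytest.fixture(scope="session")
def exposures26(scenario26) -> pd.DataFrame:
    return generate_daily_exposures(scenario26)


@pytest.fixture(scope="session")
def bundle26(scenario26, exposures26):
    return generate_weekly_mortality(scenario26, exposures26)


@pytest.fixture(scope="session")
def weekly26(bundle26) -> pd.DataFrame:
    """Weekly modeling table with covariates and the true p-score."""
    return bundle26.weekly


def simulate_simple_table(
    n: int,
    seed: int,
    mu0: float = 0.0,
    sigma0: float = 2.0,
    effects: dict[str, float] | None = None,
    x_prob: float = 0.1,
) -> pd.DataFrame:
    """Direct draw from the logistic location-scale model on binary-count
    covariates; an independent oracle for the regression machinery (no
    episode detection, no AR term)."""
    rng = np.random.default_rng(seed)
    effects = effects or {}
    table = pd.DataFrame(index=range(n))
    mu = np.full(n, mu0)
    for name, coef in effects.items():
        x = rng.binomial(2, x_prob, n).astype(float)
        table[name] = x
        mu = mu + coef * x
    table["pscore"] = rng.logistic(mu, np.exp(sigma0))
    return table
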