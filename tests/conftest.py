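import numpy as np
import pytest

from intelligrowth import (
    CeilingLaw,
    SimulationConfig,
    fit_beta_growth,
    simulate_cohort,
    squeeze_unit_interval,
)

MULTIWORD_COLS = [f"score_len{L}" for L in range(2, 8)]


def equal_weight_composite(cohort):
    """Plain mean over lengths 2..7 (valid only for complete cohorts)."""
    return cohort[MULTIWORD_COLS].mean(axis=1)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized default synthetic cohort, with listener-level scores."""
    return simulate_cohort(SimulationConfig(n_children=538, seed=1), return_listener_level=True)


@pytest.fixture(scope="session")
def big_cohort():
    """A large cohort (uniform ages) for Monte-Carlo structure checks."""
    return simulate_cohort(SimulationConfig(n_children=2000, seed=2, age_sampling="uniform"))


@pytest.fixture(scope="session")
def noceiling_config():
    return SimulationConfig(n_children=538, seed=3, ceiling=CeilingLaw.none())


@pytest.fixture(scope="session")
def noceiling_cohort(noceiling_config):
    return simulate_cohort(noceiling_config)


@pytest.fixture(scope="session")
def noceiling_fit(noceiling_cohort):
    """Beta growth fit of the equal-weight multiword composite."""
    y = squeeze_unit_interval(equal_weight_composite(noceiling_cohort).to_numpy(), len(noceiling_cohort))
    return fit_beta_growth(noceiling_cohort["age_months"].to_numpy(float), y)


@pytest.fixture(scope="session")
def flat_beta_fit():
    """Fit on data whose true distribution is constant in age (mu=.7, sigma=.2)."""
    from intelligrowth import beta_shape_from_location_scale

    rng = np.random.default_rng(42)
    ages = rng.uniform(30, 119, 4000)
    a, b = beta_shape_from_location_scale(0.7, 0.2)
    y = rng.beta(a, b, size=4000)
    return fit_beta_growth(ages, y), ages, y
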