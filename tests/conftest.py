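import numpy as np
import pytest

from grasstrend import (
    StackConfig,
    SurveyConfig,
    simulate_stack,
    simulate_survey,
)


@pytest.fixture(scope="session")
def survey():
    """One deterministic synthetic survey shared across tests.

    Seed 11 yields contaminated meadow plots, which several tests rely on.
    """
    return simulate_survey(SurveyConfig(seed=11))


@pytest.fixture(scope="session")
def annual_stack_data():
    """Small annual AGB stack with known per-pixel trend and Hurst target."""
    return simulate_stack(
        StackConfig(n_rows=10, n_cols=10, n_years=13, trend_mean=2.0,
                    trend_sd=6.0, hurst_target=0.7, innovation_sd=25.0,
                    baseline=400.0, seed=5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
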