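import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from budbird import (
    ModelSpec,
    OutbreakConfig,
    SamplerSettings,
    SimulationConfig,
    filter_routes,
    fit,
    simulate_dataset,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic survey: 3 strata x 6 routes x 12 years."""
    config = SimulationConfig(
        n_strata=3,
        routes_per_stratum=6,
        n_years=12,
        first_regional_year=5,
        observer_turnover_prob=0.15,
        seed=11,
    )
    outbreak = OutbreakConfig(pulse_start=4, pulse_length=6)
    counts, cov, latent = simulate_dataset(config, outbreak)
    return config, outbreak, counts, cov, latent


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short budworm-model fit on the compact survey (for plumbing tests)."""
    _, _, counts, cov, _ = small_dataset
    filtered, report = filter_routes(counts)
    spec = ModelSpec.build(filtered, cov)
    draws = fit(spec, SamplerSettings(chains=2, iterations=600, burn_in=300, seed=5))
    return spec, report, draws
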