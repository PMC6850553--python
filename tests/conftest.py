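import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort pushed through the full pipeline once."""
    from gencompete.recovery import cohort_pipeline
    from gencompete.simulate import SimulationConfig, simulate_cohort

    sim = simulate_cohort(SimulationConfig(n_drugs=350, n_classes=15, seed=11))
    markets, ledger = cohort_pipeline(sim)
    return sim, markets, ledger


@pytest.fixture(scope="session")
def small_markets(small_cohort) -> pd.DataFrame:
    return small_cohort[1]
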