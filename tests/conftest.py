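import pytest
from hypothesis import HealthCheck, settings

from ecckit.synthetic import DEConfig, SimulationConfig, simulate

settings.register_profile(
    "det", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def sim_dataset():
    """One moderately sized simulated study shared across test modules."""
    cfg = SimulationConfig(seed=11, n_eccdna=600, de=DEConfig(n_differential=80))
    return simulate(cfg)
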