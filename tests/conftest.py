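import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from transfic import SimConfig, build_baseline_table, simulate_universe


@pytest.fixture(scope="session")
def universe():
    """One shared synthetic universe: (catalog, collection, truth)."""
    return simulate_universe(SimConfig(seed=11))


@pytest.fixture(scope="session")
def baseline_table(universe):
    catalog, collection, _ = universe
    return build_baseline_table(catalog, collection)
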