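import numpy as np
import pytest

from hdmediate import ScenarioConfig, make_correlation_matrix, simulate_dataset


@pytest.fixture(scope="session")
def small_independent():
    """n=500, p=100, beta=0.3, 5 true mediators."""
    cfg = ScenarioConfig(scenario_id=0, n=500, p=100, prop_true=0.05,
                         beta=0.3, correlated=False, base_seed=7)
    return simulate_dataset(cfg, None, 0)


@pytest.fixture(scope="session")
def small_correlated():
    cfg = ScenarioConfig(scenario_id=0, n=500, p=60, prop_true=0.05,
                         beta=0.3, correlated=True, base_seed=7)
    corr = make_correlation_matrix(60, 7)
    return simulate_dataset(cfg, corr, 0)


@pytest.fixture(scope="session")
def big_independent():
    """n=100000, p=10, beta=0.3, 4 true mediators: large-n oracle checks."""
    cfg = ScenarioConfig(scenario_id=0, n=100_000, p=10, prop_true=0.4,
                         beta=0.3, correlated=False, base_seed=7)
    return simulate_dataset(cfg, None, 0)


@pytest.fixture(scope="session")
def null_config():
    return ScenarioConfig(scenario_id=0, n=200, p=40, prop_true=0.05,
                          beta=0.0, correlated=False, base_seed=13)
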