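import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from formose_dyn import crn_sim, io_cli

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_model():
    return crn_sim.build_formose_model()


@pytest.fixture(scope="session")
def exp013_run(default_model):
    """One EXP013 condition simulated end to end (flows + sampled traces)."""
    cfg = io_cli.preset("EXP013")
    flows, sampled = io_cli.simulate_condition(cfg, seed=3, model=default_model)
    return flows, sampled


@pytest.fixture
def rng():
    return np.random.default_rng(42)
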