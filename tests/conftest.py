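import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from r2sls.simulate import ScenarioConfig, gen_two_sample, scenario_config


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_dataset(seed=0, theta=0.1, n1=500, n2=4000, p=10, **kw):
    """Small two-sample dataset for unit tests (strong IVs, fast)."""
    cfg = ScenarioConfig(
        n1=n1, n2=n2, p_cis=p, theta=theta, reps=1, seed=seed, target_r2=0.3, **kw
    )
    data, truth = gen_two_sample(cfg, np.random.default_rng(seed))
    return data, truth


@pytest.fixture
def small_data():
    return make_dataset(seed=11)[0]
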