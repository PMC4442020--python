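import pytest
from hypothesis import HealthCheck, settings

import burnfluid as bf

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_cfg():
    return bf.SimulationConfig(
        seed=11, uop_noise_sd=0.0, rate_noise_sd=0.0, adjuster_noise_sd=0.0, diuresis_slope=0.0
    )


@pytest.fixture(scope="session")
def noiseless_cohorts(noiseless_cfg):
    derivation, validation, truth = bf.generate_cohorts(noiseless_cfg)
    return derivation, validation, truth


@pytest.fixture(scope="session")
def noiseless_models(noiseless_cohorts):
    derivation, validation, _ = noiseless_cohorts
    base = bf.BaseRateModel(derivation).fit()
    uop = bf.UrineOutputModel(derivation, base).fit()
    return base, uop


@pytest.fixture(scope="session")
def default_cfg():
    return bf.SimulationConfig(seed=3)


@pytest.fixture(scope="session")
def default_cohorts(default_cfg):
    derivation, validation, truth = bf.generate_cohorts(default_cfg)
    return derivation, validation, truth


@pytest.fixture(scope="session")
def default_models(default_cohorts):
    derivation, _, _ = default_cohorts
    base = bf.BaseRateModel(derivation).fit()
    uop = bf.UrineOutputModel(derivation, base).fit()
    return base, uop
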