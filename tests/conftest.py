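import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import epipluri as ep


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded draw from the reference simulation."""
    config = ep.default_config(seed=11)
    matrix, annotations, truth = ep.simulate(config)
    return config, matrix, annotations, truth


@pytest.fixture(scope="session")
def fitted_results(default_cohort):
    _, matrix, annotations, _ = default_cohort
    return ep.EpiPluriModel(matrix, annotations).fit()
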