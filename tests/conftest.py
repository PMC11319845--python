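import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def effects():
    from mitefear import default_effect_table

    return default_effect_table()


@pytest.fixture(scope="session")
def baseline():
    from mitefear import default_baseline

    return default_baseline()


@pytest.fixture(scope="session")
def small_design():
    """A cheap ensemble for unit tests."""
    from mitefear import ExperimentDesign

    return ExperimentDesign(n_replicates=50, horizon=30, n_founders=50, master_seed=11)
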