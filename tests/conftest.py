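import pytest

from storynf import CohortConfig, ExperimentConfig, build_assets, make_templates


@pytest.fixture(scope="session")
def small_config():
    """A reduced experiment: 20 features, well-separated templates."""
    return ExperimentConfig(
        n_features=20,
        separation=3.0,
        training=CohortConfig(n_participants=20, n_runs=2),
        pilot=CohortConfig(n_participants=10, n_runs=2),
        seed=11,
    )


@pytest.fixture(scope="session")
def assets(small_config):
    """(stations, templates, training, models, pilot, norms) for small_config."""
    return build_assets(small_config)


@pytest.fixture(scope="session")
def templates20():
    return make_templates(n_features=20, separation=2.0, seed=7)
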