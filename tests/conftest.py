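import pytest
from hypothesis import HealthCheck, settings

from chlorospec.indices import IndexCatalog, compute_feature_table
from chlorospec.synthetic import GeneratorConfig, generate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size synthetic dataset under default study conditions."""
    return generate_dataset(GeneratorConfig(n_samples=540, seed=0))


@pytest.fixture(scope="session")
def default_table(default_dataset):
    """Eleven-index feature table of the default dataset."""
    return compute_feature_table(default_dataset, IndexCatalog())


@pytest.fixture(scope="session")
def small_dataset():
    """A fast, reduced-size dataset for plumbing tests."""
    return generate_dataset(GeneratorConfig(n_samples=30, wavelength_step=2.0, seed=7))
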