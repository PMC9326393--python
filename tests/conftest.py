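import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from farmabu import SynthConfig, generate_farm, reference_catalog


@pytest.fixture(scope="session")
def catalog():
    return reference_catalog()


@pytest.fixture(scope="session")
def farm():
    """One shared synthetic 3-year farm under the study-like default conditions."""
    return generate_farm(SynthConfig(seed=123))


@pytest.fixture(scope="session")
def farm_dir(farm, tmp_path_factory):
    """The same farm written to disk as the four CSV inputs plus truth.json."""
    d = tmp_path_factory.mktemp("farm")
    farm.write(d)
    return d
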