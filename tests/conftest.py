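import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    from sydeslim.catalog import load_catalog

    return load_catalog()


@pytest.fixture(scope="session")
def scaffolds(catalog):
    from sydeslim.standins import standin_records

    return standin_records(catalog)


@pytest.fixture(scope="session")
def background():
    from sydeslim.scanner import BackgroundFrequencies

    return BackgroundFrequencies()
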