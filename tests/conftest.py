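import pytest
from hypothesis import HealthCheck, settings

from colpep import ProteinRecord, builtin_fixture, default_ruleset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def db():
    return builtin_fixture()


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


@pytest.fixture
def toy():
    return ProteinRecord(id="toy", sequence="GKGFRL")
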