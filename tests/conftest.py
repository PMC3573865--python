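import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A generated fixture directory shared across the session."""
    from plexcal.fixtures import generate_fixture

    out = tmp_path_factory.mktemp("fixture")
    generate_fixture(out, seed=1)
    return out


@pytest.fixture(scope="session")
def table1_panel(fixture_dir):
    from plexcal.panel import parse_panel

    return parse_panel(fixture_dir / "panel.tsv")
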