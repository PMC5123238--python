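import pytest

from adotrim.sim import SimConfig, build_fixture_panel, simulate_dataset


@pytest.fixture(scope="session")
def fixture_panel():
    """The two-amplicon ADO fixture panel and its planted variants."""
    return build_fixture_panel(0)


@pytest.fixture(scope="session")
def panel(fixture_panel):
    return fixture_panel[0]


@pytest.fixture(scope="session")
def planted(fixture_panel):
    return fixture_panel[1]


@pytest.fixture(scope="session")
def sd1_native(fixture_panel):
    """Full SD1 population (3186 A + 5484 B pairs) at defaults."""
    panel, planted = fixture_panel
    return simulate_dataset(SimConfig(seed=11), panel, planted)


@pytest.fixture(scope="session")
def sd2_native(fixture_panel):
    panel, planted = fixture_panel
    return simulate_dataset(SimConfig(seed=11, mode="SD2"), panel, planted)


@pytest.fixture(scope="session")
def sd1_small(fixture_panel):
    """Scaled-down SD1 population for cheap unit tests."""
    panel, planted = fixture_panel
    return simulate_dataset(SimConfig(seed=7, n_a=120, n_b=200), panel, planted)
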