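import pytest

import gpworkforce as g


@pytest.fixture(scope="session")
def toy_supply():
    """Noise-free toy supply world with known truth."""
    return g.gen_supply_fixture(g.toy_config(seed=1))


@pytest.fixture(scope="session")
def toy_need():
    return g.gen_need_fixture(g.toy_config(seed=1))


@pytest.fixture(scope="session")
def paper_like_supply():
    return g.gen_supply_fixture(g.paper_like_config(seed=3))


@pytest.fixture(scope="session")
def default_hours():
    return g.HoursProfile.from_status_means()


@pytest.fixture
def single_stratum_space():
    """Four states (one sex, one band, one location): the smallest space."""
    return g.StateSpace(
        sexes=("male",),
        age_bands=(g.AgeBand("lt45", 25, 44),),
        locations=("urban",),
    )
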