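import pytest

import sulfor


@pytest.fixture(scope="session")
def config():
    return sulfor.ModelConfig()


@pytest.fixture(scope="session")
def steady_fixture():
    return sulfor.make_fixture(sulfor.FixtureSpec(seed=0, scenario="steady"))


@pytest.fixture(scope="session")
def excursion_fixture():
    return sulfor.make_fixture(sulfor.FixtureSpec(seed=0, scenario="excursion"))


@pytest.fixture(scope="session")
def stress_fixture():
    return sulfor.make_fixture(sulfor.FixtureSpec(seed=0, scenario="stress"))


@pytest.fixture(scope="session")
def steady_traj(steady_fixture):
    forcings, d13c, _, cfg = steady_fixture
    return sulfor.integrate(cfg, forcings, d13c)


@pytest.fixture(scope="session")
def excursion_traj(excursion_fixture):
    forcings, d13c, _, cfg = excursion_fixture
    return sulfor.integrate(cfg, forcings, d13c)
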