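import pytest

from dopasight.fixtures import FixtureSpec, build_fixture, table1_fixtures


@pytest.fixture(scope="session")
def mfp3_record():
    return table1_fixtures()[0]


@pytest.fixture(scope="session")
def csga_record():
    return table1_fixtures()[1]


@pytest.fixture(scope="session")
def isolated_atom():
    return build_fixture(FixtureSpec("isolated_atom")).structure


@pytest.fixture(scope="session")
def exposed_tyr_fixture():
    return build_fixture(FixtureSpec("exposed_tyr"))


@pytest.fixture(scope="session")
def buried_tyr_fixture():
    return build_fixture(FixtureSpec("buried_tyr"))


@pytest.fixture(scope="session")
def toy_chimera_4_3():
    return build_fixture(FixtureSpec("toy_chimera", {"k": 4, "m": 3}))
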