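import pytest

from snpmeta import builtin_fixture, effects_from_table


@pytest.fixture(scope="session")
def fixture_table():
    """The built-in six-study rs798766/bladder-cancer table."""
    return builtin_fixture()


@pytest.fixture(scope="session")
def fixture_effects(fixture_table):
    return effects_from_table(fixture_table)


@pytest.fixture(scope="session")
def asian_effects(fixture_table):
    return effects_from_table(fixture_table.restrict("Asian"))


@pytest.fixture(scope="session")
def caucasian_effects(fixture_table):
    return effects_from_table(fixture_table.restrict("Caucasian"))
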