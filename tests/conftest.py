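import pytest

from pkasolv.synthetic import make_solvent_table
from pkasolv.thermochem import ThermoConstants


@pytest.fixture(scope="session")
def const() -> ThermoConstants:
    return ThermoConstants()


@pytest.fixture(scope="session")
def water():
    return make_solvent_table()["water"]


@pytest.fixture(scope="session")
def methanol():
    return make_solvent_table()["methanol"]
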