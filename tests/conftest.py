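import pytest

from srftox import load_fixture


@pytest.fixture(scope="session")
def ebro():
    return load_fixture("ebro_pesticides")


@pytest.fixture(scope="session")
def tianjin_bohai():
    return load_fixture("tianjin_bohai_pfc_ope")


@pytest.fixture(scope="session")
def xiangjiang():
    return load_fixture("xiangjiang_eds")


@pytest.fixture(scope="session")
def all_fixture_records(ebro, tianjin_bohai, xiangjiang):
    return [*ebro, *tianjin_bohai, *xiangjiang]
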