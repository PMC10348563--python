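import pytest

from riverweb import load_fixture


@pytest.fixture(scope="session")
def table3_po():
    return load_fixture("table3_po")


@pytest.fixture(scope="session")
def table3_danube():
    return load_fixture("table3_danube")


@pytest.fixture(scope="session")
def synonyms():
    return load_fixture("synonyms_po_danube")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2_global")
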