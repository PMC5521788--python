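import pytest

import invitrodose as iv


@pytest.fixture(scope="session")
def bi213():
    return iv.load_chain("bi213")


@pytest.fixture(scope="session")
def lu177():
    return iv.load_chain("lu177")


@pytest.fixture(scope="session")
def layer_table():
    return iv.packaged_layer_s_values()


@pytest.fixture(scope="session")
def cell_svals():
    return iv.packaged_cell_s_values()
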