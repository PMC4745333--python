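import pytest

from greyhrv import load_table1, load_table2, load_table3


@pytest.fixture(scope="session")
def panel():
    """The bundled per-week study panel (45 subjects x 4 weeks x 2 phases)."""
    return load_table1()


@pytest.fixture(scope="session")
def table_pre():
    """Printed 4-week pre-phase averages."""
    return load_table2()


@pytest.fixture(scope="session")
def table_post():
    """Printed 4-week post-phase averages."""
    return load_table3()
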