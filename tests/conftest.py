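import pytest

from neutrosim import load_fixture


@pytest.fixture(scope="session")
def p1():
    return load_fixture("p1")


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def p2():
    return load_fixture("p2")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3")
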