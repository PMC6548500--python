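import pytest

from ichnometry import load_basura_fixtures, load_summary_fixture


@pytest.fixture(scope="session")
def table3():
    return load_basura_fixtures("table3")


@pytest.fixture(scope="session")
def table4():
    return load_basura_fixtures("table4")


@pytest.fixture(scope="session")
def table2():
    return load_basura_fixtures("table2")


@pytest.fixture(scope="session")
def summary_rows():
    return load_summary_fixture().set_index("morphotype")
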