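import logging

import pytest

from genefam import io

logging.getLogger("genefam").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def genes():
    return io.load_table1_fixture()


@pytest.fixture(scope="session")
def pairs():
    return io.load_table2_fixture()


@pytest.fixture(scope="session")
def snp_sites():
    return io.load_table3_fixture()
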