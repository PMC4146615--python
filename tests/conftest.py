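from importlib.resources import files

import numpy as np
import pytest

from regulon_screen.io_formats import load_de_fixture

KNOWN_TARGETS = ["SCO1178", "SCO4266", "SCO1909", "SCO2478", "SCO7008"]
REGULATOR = "SCO1697"


@pytest.fixture(scope="session")
def table2():
    return load_de_fixture(files("regulon_screen.data") / "table2_fixture.tsv")


@pytest.fixture(scope="session")
def table3():
    return load_de_fixture(files("regulon_screen.data") / "table3_fixture.tsv")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
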