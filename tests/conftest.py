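import numpy as np
import pytest

from chanbench.problems import build_problem


@pytest.fixture(scope="session")
def fixture_problem():
    return build_problem("fixture_hh")


@pytest.fixture(scope="session")
def loewe_ikr():
    return build_problem("loewe_ikr")


@pytest.fixture(scope="session")
def loewe_ikur():
    return build_problem("loewe_ikur")


@pytest.fixture(scope="session")
def moreno_ina():
    return build_problem("moreno_ina")


@pytest.fixture(scope="session")
def staircase_hh():
    return build_problem("staircase_hh")


@pytest.fixture(scope="session")
def staircase_mm():
    return build_problem("staircase_mm")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
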