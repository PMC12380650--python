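import numpy as np
import pytest

from armreach.arm_model import ArmParameters, ViscosityCondition
from armreach.muscle_model import build_selection
from armreach.synthetic import make_task


@pytest.fixture(scope="session")
def arm():
    return ArmParameters.from_profile("table2_mean")


@pytest.fixture(scope="session")
def sel_s21():
    return build_selection("S21")


@pytest.fixture(scope="session")
def b10a10():
    return ViscosityCondition.named("B10A10")


@pytest.fixture(scope="session")
def t41():
    return make_task("T41")


@pytest.fixture(scope="session")
def t31():
    return make_task("T31")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
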