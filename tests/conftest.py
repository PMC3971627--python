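import numpy as np
import pytest

from ccsqc.qc import AmpliconDesign, QCParams
from ccsqc.simulate import SimParams, default_design


@pytest.fixture(scope="session")
def design() -> AmpliconDesign:
    return default_design()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def sim_params() -> SimParams:
    return SimParams(seed=42, n_templates=10)


@pytest.fixture()
def qc_params() -> QCParams:
    return QCParams(window_threshold=15.0)
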