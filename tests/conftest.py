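import warnings

import numpy as np
import pytest

from holosim.engine import StepSizeWarning
from holosim.models import molecule_declarations
from holosim.rates import default_rates


@pytest.fixture(autouse=True)
def _quiet_step_warnings():
    # desk-scale runs intentionally use coarse steps; the warning is the
    # engine's contract and is tested explicitly in test_engine
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", StepSizeWarning)
        yield


@pytest.fixture(scope="session")
def rates():
    return default_rates()


@pytest.fixture(scope="session")
def molecules(rates):
    return molecule_declarations(rates)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
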