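import numpy as np
import pytest

from ivimprefmap import AcquisitionScheme, PAPER_BVALUES
from ivimprefmap.signal_models import IvimParams, ivim_signal


@pytest.fixture(scope="session")
def scheme():
    """The 10-b pelvic acquisition scheme used throughout."""
    return AcquisitionScheme(PAPER_BVALUES, n_averages=4)


@pytest.fixture(scope="session")
def cervix_params():
    """Healthy-cervix central truth used by phantom presets."""
    return IvimParams(S0=1.0, f=0.19, D=1.3, Dstar=30.0)


@pytest.fixture(scope="session")
def noiseless_cervix_decay(scheme, cervix_params):
    return ivim_signal(cervix_params, scheme.b)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
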