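import numpy as np
import pytest

from radiosens.simulate import GroundTruthParams, simulate_cohort

#: canonical seed for cohort-level tests, fixed once for the whole suite
SEED = 12345


@pytest.fixture(scope="session")
def params():
    return GroundTruthParams()


@pytest.fixture(scope="session")
def noiseless_params():
    return GroundTruthParams().noiseless()


@pytest.fixture(scope="session")
def cohort200(params):
    """A default 200-line synthetic cohort (shared, read-only)."""
    return simulate_cohort(200, params, seed=SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
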