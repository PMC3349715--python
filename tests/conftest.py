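import warnings

import numpy as np
import pytest

from ladomics.synthetic import default_config, simulate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort (50 tumors/subtype) shared across tests."""
    return simulate_cohort(default_config(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
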