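import warnings

import numpy as np
import pytest

from condylefd.synthetic import simulate_cohort

# SVC(probability=True) is the documented way to obtain class scores in
# the scikit-learn version pinned here; silence its deprecation notice.
warnings.filterwarnings("ignore", message="The `probability` parameter")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_cohort():
    """The 220-subject cohort at the published design, seed 42."""
    return simulate_cohort(seed=42)
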