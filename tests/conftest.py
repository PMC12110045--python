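import warnings

import numpy as np
import pytest

from critdiv import BAConvergenceWarning, berger_problem, two_state_problem


@pytest.fixture(autouse=True)
def _quiet_ba_warnings():
    # near-critical solves legitimately hit the iteration cap; tests assert
    # on the returned flags instead of the warning chatter
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BAConvergenceWarning)
        yield


@pytest.fixture
def two_state_a2():
    """The worked two-state problem with distortion asymmetry a = 2."""
    return two_state_problem(2.0)


@pytest.fixture
def berger_13():
    """Berger's three-state problem at u = 1/13."""
    return berger_problem(1.0 / 13.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
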