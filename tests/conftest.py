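import numpy as np
import pytest

from mcdmri.acquisition import build_scheme_from_bvalues
from mcdmri.sphere import golden_spiral_directions


@pytest.fixture(scope="session")
def multi_shell_scheme():
    """4 b0 + two shells of 60 directions, HCP-like pulse timings."""
    dirs = golden_spiral_directions(60)
    bvalues = np.concatenate(
        [np.zeros(4), np.full(60, 1.0e9), np.full(60, 2.5e9)])
    directions = np.vstack([golden_spiral_directions(4), dirs, dirs])
    return build_scheme_from_bvalues(bvalues, directions, 10.6e-3, 43.1e-3)


@pytest.fixture(scope="session")
def single_direction_scheme():
    """b sweep along one axis for closed-form checks."""
    b = np.linspace(0, 3e9, 16)
    dirs = np.tile([[0.0, 0.0, 1.0]], (16, 1))
    return build_scheme_from_bvalues(b, dirs, 10e-3, 40e-3)


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh stream, so results
    # cannot depend on test execution order
    return np.random.default_rng(20250925)
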