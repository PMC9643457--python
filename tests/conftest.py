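import numpy as np
import pytest

from layerfluence import ConvergenceControl, build_medium


@pytest.fixture(scope="session")
def homog2():
    """Two equal 5 cm layers emulating a semi-infinite medium (a = 20 cm)."""
    return build_medium([0.1] * 2, [10.0] * 2, [5.0, 5.0], radius=20.0)


@pytest.fixture(scope="session")
def homog8():
    return build_medium([0.1] * 8, [10.0] * 8, [1.25] * 8, radius=20.0)


@pytest.fixture(scope="session")
def four_layer():
    """The 4-layer equal-property contour-study medium (a = 15 cm)."""
    return build_medium([0.1] * 4, [10.0] * 4, [0.5, 1.5, 3.0, 5.0], radius=15.0)


@pytest.fixture(scope="session")
def tight_control():
    return ConvergenceControl(rel_tol=1e-14, n_max=4000)


@pytest.fixture(scope="session")
def rho_grid():
    return np.array([0.5, 1.0, 2.0, 4.0])
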