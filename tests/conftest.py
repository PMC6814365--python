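import numpy as np
import pytest

from vflim.core import IRF, TimeAxis
from vflim.synthetic import make_irf


@pytest.fixture(scope="session")
def axis() -> TimeAxis:
    """256 bins over a 12.5 ns repetition period (80 MHz)."""
    return TimeAxis(256, 12.5)


@pytest.fixture(scope="session")
def delta(axis) -> IRF:
    """Ideal instantaneous IRF at bin 0."""
    values = np.zeros(axis.n_bins)
    values[0] = 1.0
    return IRF(axis, values)


@pytest.fixture(scope="session")
def gauss_irf(axis) -> IRF:
    """Realistic Gaussian IRF: center 1.0 ns, fwhm 0.2 ns."""
    return make_irf(axis, center=1.0, fwhm=0.2)
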