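import numpy as np
import pytest

from fretchar import synth


@pytest.fixture(scope="session")
def donor():
    """Cyan donor emulating mTurquoise2 photophysics (QY 0.93)."""
    return synth.gen_spectra((434, 474), qy=0.93, epsilon_max=30000, name="donor")


@pytest.fixture(scope="session")
def yellow_acceptor():
    """Yellow acceptor with SYFP2-like scalars."""
    return synth.gen_spectra((515, 527), qy=0.68, epsilon_max=101000, name="yellow")


@pytest.fixture(scope="session")
def red_acceptor():
    return synth.gen_spectra((569, 594), qy=0.54, epsilon_max=102000, name="red")


@pytest.fixture(scope="session")
def green_contaminant():
    """EGFP-like green species found in immature red fluorescent proteins."""
    return synth.gen_spectra((488, 507), qy=0.60, epsilon_max=55000, name="green")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
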