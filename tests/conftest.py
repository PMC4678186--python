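import numpy as np
import pytest

from phenodrought.imaging_io import PlatformConfig


@pytest.fixture(scope="session")
def cfg():
    """Full-scale platform constants."""
    return PlatformConfig()


@pytest.fixture(scope="session")
def cfg4():
    """Quarter-scale platform constants used by the synthetic scenes."""
    return PlatformConfig().scaled(4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
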