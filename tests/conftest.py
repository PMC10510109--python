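import numpy as np
import pytest
from hypothesis import settings

from memnano.core import Region

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def region_nm() -> Region:
    """The standard 1 um^2 plasma-membrane sheet (nm units)."""
    return Region(1000.0, 1000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
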