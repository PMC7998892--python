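import numpy as np
import pytest

from naagif.materials import default_materials
from naagif.structure import GifDesign


@pytest.fixture(scope="session")
def materials():
    return default_materials()


@pytest.fixture(scope="session")
def reference_design():
    """The full two-stack geometry of the reference simulation study."""
    return GifDesign()


@pytest.fixture(scope="session")
def small_design():
    """Reduced period count for fast unit tests; same physics."""
    return GifDesign(n_periods_top=60, n_periods_bottom=60)


@pytest.fixture(scope="session")
def coarse_grid():
    return np.arange(400.0, 1000.1, 2.0)
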