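import numpy as np
import pytest

from muxecog.io import GridGeometry


@pytest.fixture
def grid16():
    return GridGeometry(rows=16, cols=16, pitch_um=500.0, electrode_diameter_um=300.0)


@pytest.fixture
def small_grid():
    return GridGeometry(rows=4, cols=3, pitch_um=500.0, electrode_diameter_um=300.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
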