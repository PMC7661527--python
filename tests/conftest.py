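import numpy as np
import pytest

from seesaw.prep import VolumeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def affine_3mm():
    """3 mm isotropic grid whose voxel (10, 12, 8) sits at MNI (0, 0, 0)."""
    aff = np.diag([3.0, 3.0, 3.0, 1.0])
    aff[:3, 3] = [-30.0, -36.0, -24.0]
    return aff


@pytest.fixture
def small_volume(rng, affine_3mm):
    data = rng.standard_normal((6, 6, 5, 40))
    return VolumeSeries(data, affine_3mm, tr=2.0)
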