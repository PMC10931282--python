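import numpy as np
import pytest

from epidmvct.geometry import AcquisitionGeometry, VolumeImage
from epidmvct.phantom import build_thorax_phantom, default_thorax_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_geometry():
    """Half-scale acquisition: 320x320 native detector at 1.344 mm."""
    return AcquisitionGeometry(detector_rows=320, detector_cols=320,
                               detector_pitch=1.344)


@pytest.fixture(scope="session")
def small_phantom():
    """Small thorax phantom on a fine simulation grid (fits a 32x32x8 MVCT)."""
    return build_thorax_phantom((128, 128, 8), (1.0, 1.0, 3.0),
                                default_thorax_spec(scale=0.2))


@pytest.fixture
def cube_volume():
    """Uniform 20 mm attenuation cube centered on the isocenter."""
    return VolumeImage.centered(np.full((10, 10, 10), 0.01), (2.0, 2.0, 2.0))
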