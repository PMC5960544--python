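import numpy as np
import pytest

from nacradiomics.param_maps import DceSeries
from nacradiomics.synthetic_data import PhantomSpec, make_phantom

TIMES = np.array([0.0, 90.0, 180.0, 270.0, 360.0, 450.0])


@pytest.fixture(scope="session")
def times():
    return TIMES.copy()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small heterogeneous phantom with zero noise (session-cached)."""
    return make_phantom(PhantomSpec(grid_shape=(12, 12, 10), noise_sigma=0.0,
                                    seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def series_from_enhancement(enh, times=TIMES, s0=100.0):
    """Build a 1-voxel DceSeries whose relative enhancement equals ``enh``."""
    enh = np.asarray(enh, dtype=float)
    sig = s0 * (1.0 + enh)
    return DceSeries(sig.reshape(1, 1, 1, -1), times[: enh.size])
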