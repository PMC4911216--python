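import numpy as np
import pytest

from cortexmaps import synth
from cortexmaps.map_stats import OPMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ideal_pinwheel(shape=(41, 41), center=(20, 20), sign=+1):
    """Complex field with a single orientation singularity of the given sign."""
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]].astype(float)
    w = (xx - center[1]) + 1j * (yy - center[0])
    if sign < 0:
        w = np.conj(w)
    mag = np.abs(w)
    return OPMap(np.where(mag > 0, w / np.where(mag == 0, 1, mag), 1.0))


@pytest.fixture(scope="session")
def parametric_truth():
    """One parametric ground-truth map pair shared across read-only tests."""
    return synth.synth_maps("parametric", seed=3, size=192, wavelength=44.0)
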