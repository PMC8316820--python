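import numpy as np
import pytest

import zoomsid as z


@pytest.fixture(scope="session")
def panel():
    return z.load_panel()


@pytest.fixture(scope="session")
def tree():
    return z.load_taxonomy()


@pytest.fixture
def make_peaklist():
    """Peak list from plain masses (uniform intensity, high S/N)."""

    def _make(masses, specimen_id="S1", intensities=None):
        m = np.asarray(sorted(masses), dtype=float)
        inten = (np.asarray(intensities, dtype=float)
                 if intensities is not None else np.ones_like(m))
        return z.PeakList(m, inten, np.full(m.size, 10.0),
                          specimen_id=specimen_id)

    return _make


@pytest.fixture
def flat_spectrum():
    """Uniform 0.05 Da grid over a narrow window, zero intensity."""

    def _make(lo=1000.0, hi=1200.0, step=0.05):
        mz = np.arange(lo, hi + step / 2, step)
        return z.RawSpectrum(mz, np.zeros_like(mz), specimen_id="S1")

    return _make
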