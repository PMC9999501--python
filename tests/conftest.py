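import numpy as np
import pytest

from pymbms import IonRoleMap, SpectraMatrix


@pytest.fixture
def ions():
    return IonRoleMap()


@pytest.fixture
def tiny_matrix():
    """Two samples over three bins, raw intensities."""
    return SpectraMatrix(
        sample_ids=["a", "b"],
        mz=np.array([50, 51, 52]),
        intensities=np.array([[1.0, 1.0, 2.0], [2.0, 3.0, 5.0]]),
    )


@pytest.fixture
def replicate_matrix():
    """Two samples, two instrument replicates each."""
    return SpectraMatrix(
        sample_ids=["a", "a", "b", "b"],
        replicate_ids=["r1", "r2", "r1", "r2"],
        mz=np.array([50, 51]),
        intensities=np.array([[0.2, 0.8], [0.4, 0.6], [1.0, 1.0], [3.0, 1.0]]),
    )


@pytest.fixture
def full_axis_matrix(ions):
    """One spectrum over the full 30-450 axis with known mass placement:
    0.20 at m/z 77, 0.10 at 94, 0.05 at 122, remainder at non-aromatic
    bins (40 and 300)."""
    mz = np.arange(30, 451)
    inten = np.zeros((1, len(mz)))
    inten[0, np.searchsorted(mz, 77)] = 0.20
    inten[0, np.searchsorted(mz, 94)] = 0.10
    inten[0, np.searchsorted(mz, 122)] = 0.05
    inten[0, np.searchsorted(mz, 40)] = 0.50
    inten[0, np.searchsorted(mz, 300)] = 0.15
    return SpectraMatrix(sample_ids=["s1"], mz=mz, intensities=inten)
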