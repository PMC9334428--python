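import numpy as np
import pytest

from iccsync import simulate


def anova_icc(X):
    """Two-way ANOVA mean-squares oracle for ICC(2,M) and ICC(3,M).

    Rows of X are targets (time points), columns are raters (subjects).
    Independent of the moment-matrix implementation.
    """
    n, M = X.shape
    gm = X.mean()
    rm = X.mean(axis=1)
    cm = X.mean(axis=0)
    BMS = M * ((rm - gm) ** 2).sum() / (n - 1)
    JMS = n * ((cm - gm) ** 2).sum() / (M - 1)
    EMS = ((X - rm[:, None] - cm[None, :] + gm) ** 2).sum() / ((n - 1) * (M - 1))
    icc2k = (BMS - EMS) / (BMS + (JMS - EMS) / n)
    icc3k = (BMS - EMS) / BMS
    return icc2k, icc3k


@pytest.fixture(scope="session")
def default_design():
    return simulate.SyntheticDesign(seed=3)


@pytest.fixture(scope="session")
def default_dataset(default_design):
    return simulate.simulate_dataset(default_design, rng=3)


@pytest.fixture(scope="session")
def default_voxels(default_dataset):
    """(V, n, M) in-mask voxel matrices of the default synthetic dataset."""
    ds = default_dataset
    return np.moveaxis(ds["data"][:, ds["mask"], :], 0, 2)
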