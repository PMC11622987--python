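import numpy as np
import pytest

from nganet.atlas_io import AtlasMap, LabeledVolume
from nganet.synthetic_data import SyntheticSpec, make_atlas


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_atlas():
    """4x4x4 grid, 3 regions + background."""
    labels = np.zeros((4, 4, 4), dtype=np.int64)
    labels[0, :2, :2] = 1          # 4 voxels... plus one extra below
    labels[1, 0, 0] = 1            # region 1: 5 voxels
    labels[2:, :, :2] = 2
    labels[3, 3, 3] = 3
    names = {1: "alpha", 2: "beta", 3: "gamma"}
    return AtlasMap(labels=labels, names=names, k=3)


@pytest.fixture(scope="session")
def tiny_fmri(tiny_atlas):
    grid = np.arange(4 * 4 * 4 * 6, dtype=float).reshape(4, 4, 4, 6)
    return LabeledVolume(grid=grid, modality="fMRI")


@pytest.fixture(scope="session")
def tiny_mri(tiny_atlas):
    return LabeledVolume(grid=np.full((4, 4, 4), 7.0), modality="MRI")


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def default_atlas(default_spec):
    return make_atlas(default_spec)
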