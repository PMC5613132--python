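import numpy as np
import pytest

from latmap import laterality as lat
from latmap import synthetic as syn
from latmap.volumes import RoiMask, RoiPair, StatMap

GRID = (64, 64, 35)


@pytest.fixture(scope="session")
def grid_affine():
    return syn.default_affine(GRID, 2.0)


@pytest.fixture(scope="session")
def roi_pair():
    return syn.make_roi_pair(GRID)


@pytest.fixture(scope="session")
def cortex_masks():
    return syn.make_cortex_masks(GRID)


@pytest.fixture(scope="session")
def cohort63():
    """One seeded default 63-subject cohort shared across tests."""
    spec = syn.CohortSpec(seed=42)
    maps, metas, truth = syn.simulate_cohort(spec)
    return spec, maps, metas, truth


@pytest.fixture
def toy_roi_map():
    """A 40-voxel left ROI whose two largest Z values are 10 and 8 (rest 1),
    paired with a right ROI of small values: the worked thresholding example
    with mean-of-top-5% = 9 and adaptive threshold 4.5."""
    shape = (10, 8, 2)
    data = np.zeros(shape)
    left = np.zeros(shape, dtype=bool)
    left[0:5, 0:4, 0:2] = True  # 40 voxels
    right = np.zeros(shape, dtype=bool)
    right[5:10, 0:4, 0:2] = True
    data[left] = 1.0
    data[0, 0, 0] = 10.0
    data[0, 0, 1] = 8.0
    data[right] = 0.5
    statmap = StatMap(data=data, affine=np.eye(4), subject_id="toy")
    pair = RoiPair(left=RoiMask(data=left, side="left", label="L"),
                   right=RoiMask(data=right, side="right", label="R"))
    return statmap, pair
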