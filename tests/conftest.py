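import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from trusrad.synthetic import CohortConfig, gen_feature_table
from trusrad.volumes import ROIVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest separable cohort reused across classifier tests."""
    table, informative = gen_feature_table(CohortConfig(
        n_benign=80, n_malignant=80, p_features=12, k_informative=4,
        effect_size=1.5, block_rho=0.2, seed=11,
    ))
    return table, informative


def random_masked_grid(rng, max_extent=5, n_levels=4):
    """A random small level grid with a random (nonempty) mask."""
    shape = tuple(int(rng.integers(2, max_extent + 1)) for _ in range(3))
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < 0.7
    while mask.sum() < 2:
        mask = rng.random(shape) < 0.7
    levels = np.where(mask, levels, 0)
    return levels.astype(np.int64), mask


def random_roi(rng, extent=5):
    shape = (extent, extent, extent)
    vol = rng.random(shape) * 200
    mask = rng.random(shape) < 0.8
    while mask.sum() < 8:
        mask = rng.random(shape) < 0.8
    return ROIVolume(vol, mask)
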