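import numpy as np
import pytest

from pallidoparc.cbp_engine import DensityMap
from pallidoparc.synthetic_cohort import CohortConfig


@pytest.fixture
def small_config():
    """A fast, deterministic cohort configuration for unit tests."""
    return CohortConfig(
        n_subjects=4,
        grid_shape=(14, 18, 14),
        voxel_size_mm=1.25,
        noise_cv=0.2,
        jitter_sd_mm=0.3,
        rng_seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20210914)


def random_density_maps(rng, n_maps=3, shape=(6, 7, 5), p_zero=0.3):
    """Random nonnegative maps over a random ROI, with exact ties planted."""
    roi = rng.random(shape) < 0.7
    if not roi.any():
        roi[tuple(s // 2 for s in shape)] = True
    maps = []
    for t in range(n_maps):
        vals = rng.gamma(2.0, 1.0, size=shape)
        vals[rng.random(shape) < p_zero] = 0.0
        vals = np.where(roi, vals, 0.0)
        maps.append(DensityMap(values=vals, seed_roi=roi, target_label=f"t{t}"))
    # plant exact ties and an all-zero voxel inside the ROI
    roi_idx = np.argwhere(roi)
    tie = tuple(roi_idx[0])
    zero = tuple(roi_idx[-1])
    for m in maps:
        m.values[tie] = 1.5
        m.values[zero] = 0.0
    return maps
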