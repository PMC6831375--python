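import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from hncpipe import PhantomSpec, generate_pet_phantom, segment_fixed_threshold


@pytest.fixture
def small_phantom():
    """A heterogeneous ~600-voxel tumor phantom plus its segmentation."""
    spec = PhantomSpec(
        grid_shape=(24, 24, 24),
        voxel_spacing_mm=(2.0, 2.0, 2.0),
        tumor_radii_mm=(10.0, 9.0, 8.0),
        tumor_mean_suv=8.0,
        heterogeneity_sigma=0.3,
        heterogeneity_correlation_mm=4.0,
        rng_seed=11,
    )
    volume, true_mask = generate_pet_phantom(spec)
    roi = np.ones(spec.grid_shape, dtype=bool)
    seg = segment_fixed_threshold(volume, roi)
    return spec, volume, true_mask, seg


def random_quantized(rng, shape=(6, 6, 6), n_bins=8, p_mask=0.8):
    """A random level grid + mask for oracle-equivalence checks."""
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_bins + 1, size=int(mask.sum()))
    return levels, mask
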