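import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from pettex import PhantomConfig, generate_phantom


def random_masked_grid(rng, shape=(5, 5, 5), n_levels=6, p_mask=0.75):
    """A random quantized VOI: levels 1..n_levels inside a random mask."""
    while True:
        mask = rng.random(shape) < p_mask
        if mask.sum() >= 4:
            break
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, int(mask.sum()))
    return levels, mask


@pytest.fixture(scope="session")
def small_phantom():
    """A compact noisy lesion used by segmentation/texture integration tests."""
    cfg = PhantomConfig(
        shape=(24, 24, 20),
        tumor_center_mm=(51.0, 62.0, 31.0),
        tumor_semiaxes_mm=(14.0, 14.0, 12.0),
        heterogeneity_amplitude=2.0,
        seed=11,
    )
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomConfig(seed=3))
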