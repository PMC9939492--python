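import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from atlasguide import (
    DisplacementField,
    ImageGrid,
    MaskVolume,
    ScalarVolume,
    build_guidance_set,
)


@pytest.fixture
def grid8():
    return ImageGrid((8, 8, 8), (1.0, 1.2, 0.9), (0.0, -1.0, 0.5))


def smooth_random_volume(grid, seed, sigma=1.2):
    rng = np.random.default_rng(seed)
    return ScalarVolume(grid, gaussian_filter(rng.standard_normal(grid.shape), sigma,
                                              mode="nearest"))


def smooth_random_field(grid, seed, amplitude=0.4, sigma=1.5):
    """Small smooth displacement guaranteed fold-free at this amplitude."""
    rng = np.random.default_rng(seed)
    u = np.stack(
        [gaussian_filter(rng.standard_normal(grid.shape), sigma, mode="nearest")
         for _ in range(3)],
        axis=-1,
    )
    u *= amplitude / np.abs(u).max()
    return DisplacementField(grid, u)


def ball_mask(grid, center_offset=(0, 0, 0), radius=2.5):
    x = grid.world_coordinates()
    lo, hi = grid.extent()
    c = (np.asarray(lo) + np.asarray(hi)) / 2 + np.asarray(center_offset, dtype=float)
    return MaskVolume(grid, (np.sum((x - c) ** 2, axis=-1) <= radius**2).astype(np.uint8))


def toy_guidance(grid, jitter=0.0):
    """Four ball masks in the guidance layout used across registration tests."""
    return build_guidance_set({
        "BP": ball_mask(grid, (0, 0, 0), 3.4),
        "LLV": ball_mask(grid, (1.2 + jitter, 0.3, 0), 1.4),
        "RLV": ball_mask(grid, (-1.2, 0.3 - jitter, 0), 1.4),
        "FV": ball_mask(grid, (0, -1.4, 0.8 + jitter), 1.1),
    })
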