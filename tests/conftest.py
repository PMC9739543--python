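"""Shared fixtures: small synthetic scenes and tile datasets.

Everything is generated programmatically and seeded, so the suite needs no
stored image data.
"""

from __future__ import annotations

import numpy as np
import pytest

from blebcount.scenes import SceneSpec, generate_scene
from blebcount.tiling import TilingConfig, extract_tiles, plan_tiles
from blebcount.unet import normalize_tile


def distractor_scene_spec(seed: int, n_blebs: int = 7) -> SceneSpec:
    """A scene with qualifying blebs plus distractors that each violate
    exactly one post-processing criterion (span, shift, or size)."""
    return SceneSpec(
        seed=seed,
        shape=(24, 176, 176),
        n_blebs=n_blebs,
        n_short_blebs=3,   # span < 5 only
        n_small_blebs=3,   # size < 100 voxels only
        n_travel_segments=3,  # centroid shift > 15 px only
        n_specks=8,
    )


def scene_tile_pairs(seed: int, tile_side: int = 64):
    """All (normalized image tile, mask tile) pairs of one scene."""
    stack, mask, truth = generate_scene(distractor_scene_spec(seed))
    cfg = TilingConfig(tile_side=tile_side)
    grid = plan_tiles(stack.shape[1:], cfg)
    pairs = []
    for z in range(stack.shape[0]):
        for img, msk in zip(extract_tiles(stack[z], grid), extract_tiles(mask[z], grid)):
            pairs.append((normalize_tile(img), msk.astype(np.uint8)))
    return pairs


@pytest.fixture(scope="session")
def small_scene():
    """A compact default scene: (stack, bleb_mask, truth)."""
    return generate_scene(SceneSpec(seed=11))


@pytest.fixture(scope="session")
def distractor_scene():
    """(stack, bleb_mask, truth) for a scene with one-criterion distractors."""
    return generate_scene(distractor_scene_spec(seed=5))
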