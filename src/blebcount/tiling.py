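"""Cropping slices into fixed-size overlapping tiles and stitching them back.

The network consumes fixed 320x320 tiles; full slices are covered by a grid
of tiles whose origins advance by ``stride = floor(side * (1 - overlap))``
(304 px at the defaults: 320 px side, 5% overlap).  The final origin on
each axis is clamped so the last tile abuts the image border, and slices
smaller than the tile side are zero-padded up to it, so every source pixel
is covered by at least one tile.  Overlapping predictions are merged by a
per-pixel maximum of the bleb-channel probability, which is seam-robust and
errs toward sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["TilingConfig", "TileGrid", "plan_tiles", "extract_tiles", "stitch_tiles"]


@dataclass
class TilingConfig:
    tile_side: int = 320
    overlap_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.tile_side < 1:
            raise ValueError("tile_side must be >= 1")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")

    @property
    def stride(self) -> int:
        return max(int(self.tile_side * (1.0 - self.overlap_fraction)), 1)


@dataclass(frozen=True)
class TileGrid:
    """Planned tile origins for one slice shape.

    ``origins`` are top-left ``(y, x)`` corners in the coordinates of the
    (possibly zero-padded) canvas whose shape is ``padded_shape``.
    """

    origins: tuple[tuple[int, int], ...]
    side: int
    slice_shape: tuple[int, int]
    padded_shape: tuple[int, int]


def _axis_origins(dim: int, side: int, stride: int) -> list[int]:
    if dim <= side:
        return [0]
    origins = list(range(0, dim - side + 1, stride))
    if origins[-1] != dim - side:
        origins.append(dim - side)  # clamp so the last tile abuts the border
    return origins


def plan_tiles(slice_shape: tuple[int, int], config: TilingConfig | None = None) -> TileGrid:
    """Plan a covering grid of ``side x side`` tiles for one 2D slice."""
    config = config or TilingConfig()
    ny, nx = slice_shape
    if ny < 1 or nx < 1:
        raise ValueError("slice dimensions must be >= 1")
    side, stride = config.tile_side, config.stride
    padded = (max(ny, side), max(nx, side))
    ys = _axis_origins(padded[0], side, stride)
    xs = _axis_origins(padded[1], side, stride)
    origins = tuple((y, x) for y in ys for x in xs)
    return TileGrid(origins=origins, side=side, slice_shape=(ny, nx), padded_shape=padded)


def extract_tiles(slice_image: np.ndarray, grid: TileGrid) -> list[np.ndarray]:
    """Cut a slice into the grid's tiles; padded regions are zero-filled."""
    if slice_image.shape != grid.slice_shape:
        raise ValueError(
            f"slice shape {slice_image.shape} does not match grid {grid.slice_shape}"
        )
    canvas = slice_image
    if grid.padded_shape != grid.slice_shape:
        canvas = np.zeros(grid.padded_shape, dtype=slice_image.dtype)
        canvas[: slice_image.shape[0], : slice_image.shape[1]] = slice_image
    s = grid.side
    return [canvas[y : y + s, x : x + s].copy() for y, x in grid.origins]


def stitch_tiles(tile_maps: Sequence[np.ndarray], grid: TileGrid) -> np.ndarray:
    """Merge per-tile maps into a full-slice map by per-pixel maximum.

    Padded margins are cropped away, so the output has the original slice
    shape.
    """
    if len(tile_maps) != len(grid.origins):
        raise ValueError(
            f"expected {len(grid.origins)} tile maps, got {len(tile_maps)}"
        )
    s = grid.side
    canvas = np.full(grid.padded_shape, -np.inf, dtype=float)
    for (y, x), tile in zip(grid.origins, tile_maps):
        if tile.shape != (s, s):
            raise ValueError(f"tile map shape {tile.shape} != ({s}, {s})")
        region = canvas[y : y + s, x : x + s]
        np.maximum(region, tile, out=region)
    return canvas[: grid.slice_shape[0], : grid.slice_shape[1]]
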