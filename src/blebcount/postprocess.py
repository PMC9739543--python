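"""Three-step 3D post-processing of per-slice binary segmentations.

The 2D network labels bright roundish features slice by slice; three
filters, applied in order, restore 3D object identity and reject the known
failure modes:

1. **Slice-thickness filter** — a real bleb persists through the stack:
   every object must span at least ``min_slices`` z slices (default 5).
2. **Travelling-vector elimination** — bright axonal segments appear to
   shift through the z-stack as neighbouring segments come into focus;
   any object whose per-slice centroid moves more than
   ``max_centroid_shift`` pixels (default 15) between consecutive slices
   is eliminated whole, retaining the static circular blebs.
3. **Opening and size threshold** — per-slice morphological opening
   (erosion then dilation) followed by removal of objects smaller than
   ``min_size`` voxels (default 100) suppresses small speckled artifacts.

Objects are 3D connected components (26-neighbourhood by default); the
size threshold counts total 3D voxels after opening (a per-slice 2D
variant is available via ``size_measure``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

__all__ = [
    "PostprocessConfig",
    "BlebObject",
    "BlebCatalog",
    "open_binary",
    "assemble_objects",
    "filter_slice_thickness",
    "filter_travelling",
    "filter_size",
    "count_blebs",
]


@dataclass
class PostprocessConfig:
    min_slices: int = 5           # the user-defined "x": minimum z persistence
    max_centroid_shift: float = 15.0  # px, consecutive-slice movement threshold
    min_size: int = 100           # voxels, after opening
    opening_radius: int = 1       # disc radius for the per-slice opening
    connectivity: int = 26        # 3D neighbourhood: 6 or 26
    size_measure: str = "3d"      # '3d' total voxels or '2d' max per-slice area

    def __post_init__(self) -> None:
        if self.min_slices < 1:
            raise ValueError("min_slices must be >= 1")
        if self.max_centroid_shift < 0:
            raise ValueError("max_centroid_shift must be >= 0")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.size_measure not in ("3d", "2d"):
            raise ValueError("size_measure must be '3d' or '2d'")


@dataclass(eq=False)  # identity equality: fields hold arrays
class BlebObject:
    """One 3D connected object assembled from a binary stack."""

    id: int
    zs: np.ndarray                 # distinct occupied z indices, ascending
    centroids: np.ndarray          # (span, 2) per-slice (y, x) centroids
    voxel_count: int
    bbox: tuple[int, int, int, int, int, int]  # z0, z1, y0, y1, x0, x1
    voxel_index: np.ndarray        # sorted flat indices into the stack
    shape: tuple[int, int, int]

    @property
    def span(self) -> int:
        return len(self.zs)

    def max_consecutive_shift(self) -> float:
        if self.span < 2:
            return 0.0
        return float(np.hypot(*(np.diff(self.centroids, axis=0).T)).max())

    def max_slice_area(self) -> int:
        zz = np.unravel_index(self.voxel_index, self.shape)[0]
        return int(np.bincount(zz).max())

    def static_centroid(self) -> tuple[float, float]:
        return tuple(self.centroids.mean(axis=0))


@dataclass
class BlebCatalog:
    """Surviving objects plus provenance of the filtering run."""

    objects: list[BlebObject]
    config: PostprocessConfig
    eliminations: dict[str, int] = field(default_factory=dict)
    shape: tuple[int, int, int] | None = None

    @property
    def count(self) -> int:
        return len(self.objects)

    def survivor_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=np.uint8)
        for obj in self.objects:
            mask.ravel()[obj.voxel_index] = 1
        return mask

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "id": o.id,
                    "slice_span": o.span,
                    "voxel_count": o.voxel_count,
                    "z0": int(o.zs[0]),
                    "z1": int(o.zs[-1]),
                    "centroid_y": o.static_centroid()[0],
                    "centroid_x": o.static_centroid()[1],
                    "max_shift": o.max_consecutive_shift(),
                }
                for o in self.objects
            ]
        )

    def provenance(self) -> dict:
        import dataclasses

        return {
            "config": dataclasses.asdict(self.config),
            "eliminations": dict(self.eliminations),
            "count": self.count,
        }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def open_binary(binary_stack: np.ndarray, radius: int = 1) -> np.ndarray:
    """Per-slice 2D morphological opening (erosion then dilation) with a
    disc structuring element; pixels outside the image count as background
    for the erosion."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    stack = np.asarray(binary_stack) > 0
    if radius == 0:
        return stack.astype(np.uint8)
    selem = disk(radius)
    out = np.zeros_like(stack, dtype=np.uint8)
    for z in range(stack.shape[0]):
        out[z] = ndimage.binary_opening(stack[z], structure=selem)
    return out


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)


def assemble_objects(binary_stack: np.ndarray, connectivity: int = 26) -> list[BlebObject]:
    """Group a binary stack into 3D connected components.

    Each component's per-slice centroid is the mean (y, x) of its voxels on
    that slice; components are numbered in scan order.
    """
    stack = np.asarray(binary_stack) > 0
    labels, n = ndimage.label(stack, structure=_structure(connectivity))
    objects: list[BlebObject] = []
    if n == 0:
        return objects
    flat = labels.ravel()
    order = np.argsort(flat, kind="stable")
    nz_start = np.searchsorted(flat[order], 1)
    order = order[nz_start:]
    boundaries = np.searchsorted(flat[order], np.arange(1, n + 2))
    for i in range(n):
        idx = np.sort(order[boundaries[i] : boundaries[i + 1]])
        zz, yy, xx = np.unravel_index(idx, stack.shape)
        zs = np.unique(zz)
        centroids = np.array(
            [[yy[zz == z].mean(), xx[zz == z].mean()] for z in zs]
        )
        objects.append(
            BlebObject(
                id=i,
                zs=zs,
                centroids=centroids,
                voxel_count=len(idx),
                bbox=(int(zz.min()), int(zz.max()), int(yy.min()),
                      int(yy.max()), int(xx.min()), int(xx.max())),
                voxel_index=idx,
                shape=stack.shape,
            )
        )
    return objects


def filter_slice_thickness(objects: Sequence[BlebObject], min_slices: int = 5):
    """Keep objects persisting through at least ``min_slices`` z slices."""
    return [o for o in objects if o.span >= min_slices]


def filter_travelling(objects: Sequence[BlebObject], max_shift: float = 15.0):
    """Eliminate any object whose centroid moves more than ``max_shift``
    pixels between consecutive occupied slices (whole-object removal)."""
    return [o for o in objects if o.max_consecutive_shift() <= max_shift]


def filter_size(objects: Sequence[BlebObject], min_size: int = 100,
                size_measure: str = "3d"):
    """Keep objects of at least ``min_size`` (inclusive): total 3D voxels,
    or the largest per-slice 2D area with ``size_measure='2d'``."""
    if size_measure == "3d":
        return [o for o in objects if o.voxel_count >= min_size]
    return [o for o in objects if o.max_slice_area() >= min_size]


def _mask_from(objects: Sequence[BlebObject], shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=np.uint8)
    for o in objects:
        mask.ravel()[o.voxel_index] = 1
    return mask


def count_blebs(binary_stack: np.ndarray, config: PostprocessConfig | None = None) -> BlebCatalog:
    """Run the full three-step filter pipeline and count surviving blebs.

    Step 1 assembles 3D objects and applies the slice-thickness filter,
    step 2 the travelling-vector elimination, step 3 the per-slice opening
    followed by re-assembly and the size threshold.  The catalog records
    how many objects each step eliminated.
    """
    cfg = config or PostprocessConfig()
    stack = np.asarray(binary_stack)
    if stack.ndim != 3:
        raise ValueError(f"expected a (z, y, x) binary stack, got {stack.shape}")
    eliminations: dict[str, int] = {}

    objects = assemble_objects(stack, cfg.connectivity)
    eliminations["assembled"] = len(objects)
    kept = filter_slice_thickness(objects, cfg.min_slices)
    eliminations["slice_thickness"] = len(objects) - len(kept)

    survivors = filter_travelling(kept, cfg.max_centroid_shift)
    eliminations["travelling"] = len(kept) - len(survivors)

    opened = open_binary(_mask_from(survivors, stack.shape), cfg.opening_radius)
    reassembled = assemble_objects(opened, cfg.connectivity)
    eliminations["opening"] = len(survivors) - len(reassembled)
    final = filter_size(reassembled, cfg.min_size, cfg.size_measure)
    eliminations["size"] = len(reassembled) - len(final)

    return BlebCatalog(objects=final, config=cfg, eliminations=eliminations,
                       shape=tuple(stack.shape))
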