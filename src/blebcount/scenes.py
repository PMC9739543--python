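"""Synthetic optic-nerve z-stacks with exact ground truth.

The generator plants, over a noisy background, the object classes the
pipeline must tell apart in real neurofilament-labelled nerves:

* **axons** — thin bright tubes running along the nerve (x) axis; scene
  dressing, never catalogued;
* **blebs** — bright ellipsoids persisting across several z slices with a
  *static* centroid (the detection target);
* **travelling segments** — bright per-slice discs whose centroid shifts by
  a constant displacement from slice to slice, mimicking bright axonal
  segments that come into focus at shifting positions through the stack;
* **specks** — small single-slice pixel clusters mimicking speckled
  artifacts.

Distractor sub-populations (short-span blebs, under-size blebs) let a scene
plant objects violating exactly one post-processing criterion each.  Every
planted object is catalogued with its exact geometry, so downstream filters
can be checked against truth rather than against another segmentation.

Scenes make no attempt at photorealism (no light-sheet optics, clearing
artifacts or nerve curvature); they reproduce the geometric and intensity
structure the post-processing filters key on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .postprocess import PostprocessConfig

__all__ = [
    "SceneSpec",
    "PlantedObject",
    "GroundTruth",
    "generate_scene",
    "augment",
    "select_augmented",
]


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    Radii are in pixels, spans in slices, intensities in 8-bit counts.
    Defaults give a 24-slice nerve with bright, clearly supra-background
    objects separated well enough that 3D components never merge.
    """

    shape: tuple[int, int, int] = (24, 128, 128)
    n_axons: int = 5
    axon_intensity: tuple[float, float] = (70.0, 110.0)
    axon_radius: float = 1.0
    n_blebs: int = 7
    bleb_radius_range: tuple[float, float] = (4.0, 6.0)
    bleb_span_range: tuple[int, int] = (5, 9)
    bleb_intensity: tuple[float, float] = (160.0, 220.0)
    n_travel_segments: int = 3
    travel_shift: float = 18.0
    travel_width: float = 2.5
    travel_span_range: tuple[int, int] = (5, 6)
    n_specks: int = 8
    speck_size_range: tuple[int, int] = (3, 20)
    # distractor sub-populations (bleb-shaped, each failing one filter)
    n_short_blebs: int = 0
    short_bleb_span_range: tuple[int, int] = (2, 4)
    short_bleb_radius_range: tuple[float, float] = (5.0, 6.0)
    n_small_blebs: int = 0
    small_bleb_radius_range: tuple[float, float] = (1.8, 2.2)
    small_bleb_span_range: tuple[int, int] = (5, 7)
    background_mean: float = 30.0
    background_sd: float = 8.0
    min_separation: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_axons", "n_blebs", "n_travel_segments", "n_specks",
                     "n_short_blebs", "n_small_blebs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.travel_shift < 0:
            raise ValueError("travel_shift must be >= 0")
        for name in ("bleb_radius_range",
                     "short_bleb_radius_range", "small_bleb_radius_range"):
            if getattr(self, name)[0] <= 0:
                raise ValueError(f"{name} must be positive")
        nz = self.shape[0]
        for count, name in (
            (self.n_blebs, "bleb_span_range"),
            (self.n_travel_segments, "travel_span_range"),
            (self.n_small_blebs, "small_bleb_span_range"),
            (self.n_short_blebs, "short_bleb_span_range"),
        ):
            lo, hi = getattr(self, name)
            if count > 0 and not 1 <= lo <= hi <= nz:
                raise ValueError(f"{name} must fit within stack depth {nz}")


@dataclass
class PlantedObject:
    """Exact geometry of one catalogued object."""

    id: int
    cls: str  # 'bleb' | 'travel_segment' | 'speck'
    z0: int
    span: int
    centroids: list[tuple[float, float]]  # painted (y, x) centroid per slice
    voxel_count: int
    qualifies_as_bleb: bool

    def max_consecutive_shift(self) -> float:
        if len(self.centroids) < 2:
            return 0.0
        c = np.asarray(self.centroids)
        return float(np.hypot(*(np.diff(c, axis=0).T)).max())


@dataclass
class GroundTruth:
    """Catalog of planted objects plus the masks derived from them."""

    objects: list[PlantedObject] = field(default_factory=list)
    all_objects_mask: np.ndarray | None = None  # every catalogued object
    voxel_sum: float = 0.0  # sum of all painted voxel intensities

    def qualifying_ids(self) -> list[int]:
        return [o.id for o in self.objects if o.qualifies_as_bleb]

    def recompute_qualifies(self, config: PostprocessConfig) -> list[bool]:
        """Re-derive the qualifies flag from geometry and a filter config."""
        return [
            o.cls == "bleb"
            and o.span >= config.min_slices
            and o.voxel_count >= config.min_size
            and o.max_consecutive_shift() <= config.max_centroid_shift
            for o in self.objects
        ]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "id": o.id,
                    "class": o.cls,
                    "z0": o.z0,
                    "span": o.span,
                    "voxel_count": o.voxel_count,
                    "centroid_y": float(np.mean([c[0] for c in o.centroids])),
                    "centroid_x": float(np.mean([c[1] for c in o.centroids])),
                    "max_shift": o.max_consecutive_shift(),
                    "qualifies_as_bleb": o.qualifies_as_bleb,
                }
                for o in self.objects
            ]
        )


# ---------------------------------------------------------------------------
# painting helpers
# ---------------------------------------------------------------------------

def _ellipsoid_voxels(shape, zc, yc, xc, a, b, c):
    """Integer voxels inside the ellipsoid ((z-zc)/a)^2 + ... <= 1."""
    nz, ny, nx = shape
    z0, z1 = max(int(np.floor(zc - a)), 0), min(int(np.ceil(zc + a)), nz - 1)
    y0, y1 = max(int(np.floor(yc - b)), 0), min(int(np.ceil(yc + b)), ny - 1)
    x0, x1 = max(int(np.floor(xc - c)), 0), min(int(np.ceil(xc + c)), nx - 1)
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1 + 1), np.arange(y0, y1 + 1), np.arange(x0, x1 + 1),
        indexing="ij",
    )
    inside = (
        ((zz - zc) / a) ** 2 + ((yy - yc) / b) ** 2 + ((xx - xc) / c) ** 2
    ) <= 1.0
    return zz[inside], yy[inside], xx[inside]


def _capsule_pixels(shape_yx, yc, xc, uy, ux, half_len, width):
    """Pixels within ``width`` of the segment of length ``2 * half_len``
    through (yc, xc) along unit direction (uy, ux).

    When (2*yc, 2*xc) are integers the rasterized set is mirror-symmetric
    about the center, so its pixel centroid is exactly (yc, xc).
    """
    ny, nx = shape_yx
    ext = half_len + width + 1
    y0, y1 = max(int(np.floor(yc - ext)), 0), min(int(np.ceil(yc + ext)), ny - 1)
    x0, x1 = max(int(np.floor(xc - ext)), 0), min(int(np.ceil(xc + ext)), nx - 1)
    yy, xx = np.meshgrid(np.arange(y0, y1 + 1), np.arange(x0, x1 + 1), indexing="ij")
    ry, rx = yy - yc, xx - xc
    t = np.clip(ry * uy + rx * ux, -half_len, half_len)
    d2 = (ry - t * uy) ** 2 + (rx - t * ux) ** 2
    inside = d2 <= width * width
    return yy[inside], xx[inside]


class _Placer:
    """Rejection-samples object bounding boxes with a minimum separation."""

    def __init__(self, shape, separation, rng, max_tries=1000):
        self.shape = shape
        self.sep = separation
        self.rng = rng
        self.max_tries = max_tries
        self.boxes: list[tuple] = []

    def clear_of_others(self, box) -> bool:
        z0, z1, y0, y1, x0, x1 = box
        for oz0, oz1, oy0, oy1, ox0, ox1 in self.boxes:
            if (z0 - self.sep <= oz1 and oz0 <= z1 + self.sep
                    and y0 - self.sep <= oy1 and oy0 <= y1 + self.sep
                    and x0 - self.sep <= ox1 and ox0 <= x1 + self.sep):
                return False
        return True

    def commit(self, box) -> None:
        self.boxes.append(box)


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def generate_scene(spec: SceneSpec):
    """Build one scene.

    Returns ``(stack, bleb_mask, truth)``: an 8-bit ``(z, y, x)`` image
    stack, the binary training mask marking bleb-class voxels only, and the
    :class:`GroundTruth` catalog (which also carries a mask of *all*
    catalogued objects and the sum of painted intensities).  Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    image = rng.normal(spec.background_mean, spec.background_sd, spec.shape)
    bleb_mask = np.zeros(spec.shape, dtype=np.uint8)
    all_mask = np.zeros(spec.shape, dtype=np.uint8)
    placer = _Placer(spec.shape, spec.min_separation, rng)
    truth = GroundTruth()
    next_id = 0

    def paint(zz, yy, xx, intensity):
        image[zz, yy, xx] = np.maximum(image[zz, yy, xx], intensity)

    def catalog(cls, z0, span, centroids, count, voxels, is_bleb_mask):
        nonlocal next_id
        zz, yy, xx = voxels
        all_mask[zz, yy, xx] = 1
        if is_bleb_mask:
            bleb_mask[zz, yy, xx] = 1
        obj = PlantedObject(next_id, cls, z0, span, centroids, count, False)
        truth.objects.append(obj)
        next_id += 1
        return obj

    def plant_ellipsoid_bleb(span_range, radius_range, must_fit=True):
        """One static ellipsoidal bleb; returns its voxels or None."""
        for _ in range(placer.max_tries):
            span = int(rng.integers(span_range[0], span_range[1] + 1))
            r = rng.uniform(*radius_range)
            a = (span - 1) / 2.0 + 0.45  # z semi-axis giving exactly `span` slices
            zc = rng.uniform(a, nz - 1 - a) if nz - 1 - a > a else (nz - 1) / 2.0
            z0 = int(np.ceil(zc - a))
            yc = rng.uniform(r + 1, ny - 2 - r)
            xc = rng.uniform(r + 1, nx - 2 - r)
            box = (z0, z0 + span - 1, yc - r, yc + r, xc - r, xc + r)
            if not placer.clear_of_others(box):
                continue
            zz, yy, xx = _ellipsoid_voxels(spec.shape, zc, yc, xc, a, r, r)
            zs = np.unique(zz)
            if len(zs) != span:
                continue  # rasterization dropped a cap slice; resample
            placer.commit(box)
            centroids = [
                (float(yy[zz == z].mean()), float(xx[zz == z].mean())) for z in zs
            ]
            return zs[0], span, centroids, (zz, yy, xx)
        if must_fit:
            raise ValueError("could not place object; scene too crowded for spec")
        return None

    # --- travelling bright segments: elongated per-slice capsules whose
    # center shifts by a constant displacement each slice.  The capsule is
    # long enough along the motion direction that consecutive slices
    # overlap, so the object stays one 3D component (like a bright axonal
    # segment coming into focus at shifting positions).
    for _ in range(spec.n_travel_segments):
        placed = False
        for _ in range(placer.max_tries):
            span = int(rng.integers(spec.travel_span_range[0], spec.travel_span_range[1] + 1))
            w = spec.travel_width
            half_len = spec.travel_shift / 2.0 + 2.0  # guarantees z-overlap
            theta = rng.uniform(0, 2 * np.pi)
            uy, ux = np.sin(theta), np.cos(theta)
            dy, dx = spec.travel_shift * uy, spec.travel_shift * ux
            total_y, total_x = dy * (span - 1), dx * (span - 1)
            margin_y = abs(uy) * half_len + w + 1
            margin_x = abs(ux) * half_len + w + 1
            z0 = int(rng.integers(0, nz - span + 1))
            lo_y = margin_y + max(-total_y, 0)
            hi_y = ny - 1 - margin_y - max(total_y, 0)
            lo_x = margin_x + max(-total_x, 0)
            hi_x = nx - 1 - margin_x - max(total_x, 0)
            if hi_y <= lo_y or hi_x <= lo_x:
                continue
            yc, xc = rng.uniform(lo_y, hi_y), rng.uniform(lo_x, hi_x)
            # snap per-slice centers to the half-integer grid so each
            # rasterized capsule is symmetric and its centroid exact
            ys = np.rint(2 * (yc + dy * np.arange(span))) / 2.0
            xs = np.rint(2 * (xc + dx * np.arange(span))) / 2.0
            box = (z0, z0 + span - 1,
                   ys.min() - margin_y, ys.max() + margin_y,
                   xs.min() - margin_x, xs.max() + margin_x)
            if not placer.clear_of_others(box):
                continue
            placer.commit(box)
            vz, vy, vx = [], [], []
            centroids = []
            for i in range(span):
                yy, xx = _capsule_pixels((ny, nx), ys[i], xs[i], uy, ux, half_len, w)
                vz.append(np.full(len(yy), z0 + i))
                vy.append(yy)
                vx.append(xx)
                centroids.append((float(yy.mean()), float(xx.mean())))
            vox = (np.concatenate(vz), np.concatenate(vy), np.concatenate(vx))
            paint(*vox, rng.uniform(*spec.bleb_intensity))
            catalog("travel_segment", z0, span, centroids, len(vox[0]), vox, False)
            placed = True
            break
        if not placed:
            raise ValueError("could not place travelling segment; enlarge the scene")

    # --- blebs (the detection target), plus the distractor sub-populations
    for n, span_rng, rad_rng in (
        (spec.n_blebs, spec.bleb_span_range, spec.bleb_radius_range),
        (spec.n_short_blebs, spec.short_bleb_span_range, spec.short_bleb_radius_range),
        (spec.n_small_blebs, spec.small_bleb_span_range, spec.small_bleb_radius_range),
    ):
        for _ in range(n):
            z0, span, centroids, vox = plant_ellipsoid_bleb(span_rng, rad_rng)
            paint(*vox, rng.uniform(*spec.bleb_intensity))
            catalog("bleb", z0, span, centroids, len(vox[0]), vox, True)

    # --- specks: small single-slice clusters grown from a seed pixel
    for _ in range(spec.n_specks):
        for _ in range(placer.max_tries):
            size = int(rng.integers(spec.speck_size_range[0], spec.speck_size_range[1] + 1))
            z = int(rng.integers(0, nz))
            y = int(rng.integers(2, ny - 2))
            x = int(rng.integers(2, nx - 2))
            ext = int(np.ceil(np.sqrt(size))) + 1
            box = (z, z, y - ext, y + ext, x - ext, x + ext)
            if not placer.clear_of_others(box):
                continue
            placer.commit(box)
            pix = {(y, x)}
            frontier = [(y, x)]
            while len(pix) < size and frontier:
                cy, cx = frontier[int(rng.integers(len(frontier)))]
                step = [(0, 1), (0, -1), (1, 0), (-1, 0)][int(rng.integers(4))]
                ny_, nx_ = cy + step[0], cx + step[1]
                if (abs(ny_ - y) <= ext and abs(nx_ - x) <= ext
                        and 0 <= ny_ < ny and 0 <= nx_ < nx):
                    if (ny_, nx_) not in pix:
                        pix.add((ny_, nx_))
                        frontier.append((ny_, nx_))
            yy = np.array([p[0] for p in sorted(pix)])
            xx = np.array([p[1] for p in sorted(pix)])
            zz = np.full(len(yy), z)
            paint(zz, yy, xx, rng.uniform(*spec.bleb_intensity))
            catalog("speck", z, 1, [(float(yy.mean()), float(xx.mean()))],
                    len(yy), (zz, yy, xx), False)
            break
        else:
            raise ValueError("could not place speck; enlarge the scene")

    # --- axons: thin bright tubes along x, kept clear of catalogued objects
    for _ in range(spec.n_axons):
        for _ in range(placer.max_tries):
            z0 = rng.uniform(1, nz - 2)
            y0 = rng.uniform(2, ny - 3)
            r = spec.axon_radius
            box = (z0 - r, z0 + r, y0 - r, y0 + r, 0, nx - 1)
            if not placer.clear_of_others(box):
                continue
            placer.commit(box)
            zz, yy = np.meshgrid(
                np.arange(max(int(z0 - r), 0), min(int(z0 + r) + 1, nz)),
                np.arange(max(int(y0 - r), 0), min(int(y0 + r) + 1, ny)),
                indexing="ij",
            )
            inside = (zz - z0) ** 2 + (yy - y0) ** 2 <= r * r
            zs, ysel = zz[inside], yy[inside]
            intensity = rng.uniform(*spec.axon_intensity)
            for zi, yi in zip(zs, ysel):
                xs = np.arange(nx)
                paint(np.full(nx, zi), np.full(nx, yi), xs, intensity)
            break
        # axons that cannot be placed are silently skipped: they are
        # dressing, not catalogued objects

    image = np.clip(image, 0, 255)
    truth.voxel_sum = float(np.rint(image).astype(np.uint8).sum())
    for obj, flag in zip(truth.objects,
                         truth.recompute_qualifies(PostprocessConfig())):
        obj.qualifies_as_bleb = flag
    truth.all_objects_mask = all_mask
    return np.rint(image).astype(np.uint8), bleb_mask, truth


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

_ALL_OPS = ("flip_x", "flip_y", "rescale", "noise", "blur", "bias_field")


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    seed: int,
    ops: Sequence[str] | None = _ALL_OPS,
):
    """Randomly transform one training slice/tile and its mask.

    Geometric operations (flips along x and y) are applied identically to
    image and mask; intensity operations (rescale, additive noise, blur,
    multiplicative bias field) touch the image only.  Each enabled
    operation fires with probability 1/2.  ``ops=()`` (or ``None``)
    disables augmentation and returns the inputs unchanged.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask must share a 2D shape")
    if not ops:
        return image, mask
    rng = np.random.default_rng(seed)
    img = image.astype(np.float64, copy=True)
    msk = mask.copy()
    fire = {op: bool(rng.integers(2)) for op in _ALL_OPS}
    if "flip_x" in ops and fire["flip_x"]:
        img, msk = img[:, ::-1].copy(), msk[:, ::-1].copy()
    if "flip_y" in ops and fire["flip_y"]:
        img, msk = img[::-1].copy(), msk[::-1].copy()
    if "rescale" in ops and fire["rescale"]:
        img *= rng.uniform(0.7, 1.3)
    if "noise" in ops and fire["noise"]:
        img += rng.normal(0.0, 0.03 * max(img.max(), 1e-12), img.shape)
    if "blur" in ops and fire["blur"]:
        img = ndimage.gaussian_filter(img, sigma=rng.uniform(0.3, 1.2))
    if "bias_field" in ops and fire["bias_field"]:
        # smooth low-order polynomial multiplicative gain across the field
        h, w = img.shape
        if h > 1 and w > 1:
            yy, xx = np.mgrid[0:h, 0:w]
            yy = yy / (h - 1) - 0.5
            xx = xx / (w - 1) - 0.5
            coef = rng.uniform(-0.3, 0.3, size=5)
            gain = 1.0 + coef[0] * yy + coef[1] * xx + coef[2] * yy * xx \
                + coef[3] * yy**2 + coef[4] * xx**2
            img *= np.clip(gain, 0.5, 1.5)
    return np.clip(img, 0.0, None), msk


def select_augmented(n: int, fraction: float = 0.5, seed: int = 0) -> np.ndarray:
    """Indices of exactly ``round(fraction * n)`` items chosen by seeded
    shuffle (an exact subset rather than per-item coin flips)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    k = int(round(fraction * n))
    order = np.random.default_rng(seed).permutation(n)
    return np.sort(order[:k])
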