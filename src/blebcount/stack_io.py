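"""Stack and annotation I/O, pipeline configuration, logging.

Conventions used throughout the package
---------------------------------------
* Image stacks are numpy arrays with axis order ``(z, y, x)``, 0-based
  indices, and pixel centers at integer coordinates.  A single 2D image is
  a stack with ``z == 1``.
* Binary masks are ``uint8`` arrays of the same shape with values in
  ``{0, 1}``.
* ROI polygons are sequences of ``(x, y)`` vertices in pixel coordinates
  with the same origin as the image.  Pixels whose center lies inside *or
  on the boundary of* a polygon are foreground.

The annotation format is the ImageJ ROI format (single ``.roi`` files or a
``.zip`` container of them), the format produced when blebs are circled by
hand in ImageJ.  Only the planar outline types (polygon, rectangle,
freehand, oval) are supported; the slice a ROI belongs to is taken from the
ROI position field (1-based in ImageJ, converted to a 0-based z index).
"""

from __future__ import annotations

import dataclasses
import io
import logging
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml
from matplotlib.path import Path as MplPath

logger = logging.getLogger("blebcount")

__all__ = [
    "read_stack",
    "write_stack",
    "Roi",
    "read_rois",
    "write_rois",
    "rasterize_rois",
    "PipelineConfig",
    "load_config",
    "setup_logging",
]


def setup_logging(level: int = logging.INFO) -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def read_stack(path: str | Path) -> np.ndarray:
    """Read a single- or multi-page grayscale TIFF as a ``(z, y, x)`` stack.

    Integer intensities are preserved bit-exactly.  A single-page file
    yields a stack with ``z == 1``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    voxels = tifffile.imread(path)
    if voxels.ndim == 2:
        voxels = voxels[np.newaxis, ...]
    elif voxels.ndim != 3:
        raise ValueError(
            f"{path}: expected a 2D or 3D grayscale TIFF, got shape {voxels.shape}"
        )
    return voxels


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a ``(z, y, x)`` stack as a multi-page grayscale TIFF."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[np.newaxis, ...]
    if stack.ndim != 3:
        raise ValueError(f"expected a (z, y, x) stack, got shape {stack.shape}")
    # grayscale pages; without this, small z counts are guessed to be RGB
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


# ---------------------------------------------------------------------------
# ImageJ ROI format
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Roi:
    """One planar ROI: a closed polygon on a single z slice.

    ``points`` is an ``(n, 2)`` float array of ``(x, y)`` vertices, n >= 3.
    """

    z: int
    points: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("a ROI polygon needs an (n>=3, 2) vertex array")
        object.__setattr__(self, "points", pts)


# ImageJ ROI type codes with a polygon representation.
_IJ_POLYGON = 0
_IJ_RECT = 1
_IJ_OVAL = 2
_IJ_FREEHAND = 7
_IJ_TRACED = 8

_HEADER_SIZE = 64


def _decode_roi(buf: bytes, name: str | None = None) -> Roi:
    if buf[:4] != b"Iout":
        raise ValueError("not an ImageJ ROI (missing 'Iout' magic)")
    roi_type = buf[6]
    top, left, bottom, right = struct.unpack(">4h", buf[8:16])
    n = struct.unpack(">h", buf[16:18])[0]
    position = struct.unpack(">i", buf[56:60])[0]
    hdr2 = struct.unpack(">i", buf[60:64])[0]
    if 0 < hdr2 <= len(buf) - 16:
        z_pos = struct.unpack(">i", buf[hdr2 + 8 : hdr2 + 12])[0]
        if z_pos > 0:
            position = z_pos
    z = max(position - 1, 0)  # ImageJ slice positions are 1-based; 0 = unset

    if roi_type == _IJ_RECT:
        w, h = right - left, bottom - top
        if w < 1 or h < 1:
            raise ValueError("degenerate rectangle ROI")
        # Boundary-inclusive convention: vertices on the outermost pixel
        # centers, so a w x h rectangle rasterizes to exactly w*h pixels.
        pts = np.array(
            [
                (left, top),
                (left + w - 1, top),
                (left + w - 1, top + h - 1),
                (left, top + h - 1),
            ],
            dtype=float,
        )
    elif roi_type == _IJ_OVAL:
        w, h = right - left, bottom - top
        cx, cy = left + (w - 1) / 2.0, top + (h - 1) / 2.0
        theta = np.linspace(0.0, 2.0 * np.pi, 72, endpoint=False)
        pts = np.column_stack(
            [cx + (w - 1) / 2.0 * np.cos(theta), cy + (h - 1) / 2.0 * np.sin(theta)]
        )
    elif roi_type in (_IJ_POLYGON, _IJ_FREEHAND, _IJ_TRACED):
        if n < 3:
            raise ValueError(f"polygon ROI with {n} vertices")
        off = _HEADER_SIZE
        xs = np.frombuffer(buf, ">i2", count=n, offset=off).astype(float) + left
        ys = np.frombuffer(buf, ">i2", count=n, offset=off + 2 * n).astype(float) + top
        pts = np.column_stack([xs, ys])
    else:
        raise ValueError(f"ROI type {roi_type} has no polygon representation")
    return Roi(z=z, points=pts, label=name)


def _encode_roi(roi: Roi) -> bytes:
    pts = np.rint(roi.points).astype(int)
    left, top = int(pts[:, 0].min()), int(pts[:, 1].min())
    right, bottom = int(pts[:, 0].max()), int(pts[:, 1].max())
    n = len(pts)
    out = io.BytesIO()
    header = bytearray(_HEADER_SIZE)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 228)  # format version
    header[6] = _IJ_POLYGON
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    struct.pack_into(">i", header, 56, roi.z + 1)
    hdr2_offset = _HEADER_SIZE + 4 * n
    struct.pack_into(">i", header, 60, hdr2_offset)
    out.write(bytes(header))
    out.write(np.asarray(pts[:, 0] - left, dtype=">i2").tobytes())
    out.write(np.asarray(pts[:, 1] - top, dtype=">i2").tobytes())
    hdr2 = bytearray(64)
    struct.pack_into(">i", hdr2, 8, roi.z + 1)  # Z position
    out.write(bytes(hdr2))
    return out.getvalue()


def read_rois(path: str | Path) -> list[Roi]:
    """Read a single ``.roi`` file or a ``.zip`` container of ROIs."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if zipfile.is_zipfile(path):
        rois: list[Roi] = []
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                if name.lower().endswith(".roi"):
                    rois.append(_decode_roi(zf.read(name), name=Path(name).stem))
        return rois
    return [_decode_roi(path.read_bytes(), name=path.stem)]


def write_rois(rois: Sequence[Roi], path: str | Path) -> None:
    """Write ROIs: one ``.roi`` file, or a ``.zip`` container for many."""
    path = Path(path)
    if path.suffix.lower() == ".roi":
        if len(rois) != 1:
            raise ValueError("a .roi file holds exactly one ROI; use .zip")
        path.write_bytes(_encode_roi(rois[0]))
        return
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for i, roi in enumerate(rois):
            name = roi.label or f"{roi.z + 1:04d}-{i:04d}"
            zf.writestr(f"{name}.roi", _encode_roi(roi))


def rasterize_rois(rois: Sequence[Roi], shape: tuple[int, int, int]) -> np.ndarray:
    """Rasterize per-slice polygons into a binary ``(z, y, x)`` truth mask.

    A voxel is set iff its pixel center lies inside or on the boundary of a
    polygon on that slice.  ROI parts outside the image are clipped with a
    warning; slices without ROIs stay zero.
    """
    nz, ny, nx = shape
    mask = np.zeros(shape, dtype=np.uint8)
    for roi in rois:
        if not (0 <= roi.z < nz):
            raise ValueError(f"ROI slice index {roi.z} outside stack depth {nz}")
        pts = roi.points
        if (pts[:, 0].min() < 0 or pts[:, 1].min() < 0
                or pts[:, 0].max() > nx - 1 or pts[:, 1].max() > ny - 1):
            logger.warning("ROI on slice %d extends outside image; clipping", roi.z)
        x0 = max(int(np.floor(pts[:, 0].min())), 0)
        x1 = min(int(np.ceil(pts[:, 0].max())), nx - 1)
        y0 = max(int(np.floor(pts[:, 1].min())), 0)
        y1 = min(int(np.ceil(pts[:, 1].max())), ny - 1)
        if x1 < x0 or y1 < y0:
            continue
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        centers = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        # interior via even-odd crossing (contains_points closes the
        # polygon implicitly); boundary pixels, for which the crossing test
        # is unreliable, added by an explicit on-segment test
        mpath = MplPath(pts)
        inside = mpath.contains_points(centers) | _on_boundary(centers, pts)
        sub = mask[roi.z, y0 : y1 + 1, x0 : x1 + 1]
        sub |= inside.reshape(ys.shape).astype(np.uint8)
    return mask


def _on_boundary(points: np.ndarray, polygon: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """True for points within ``tol`` of any closed-polygon edge."""
    on = np.zeros(len(points), dtype=bool)
    closed = np.vstack([polygon, polygon[:1]])
    for a, b in zip(closed[:-1], closed[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d2 = ((points - a) ** 2).sum(axis=1)
        else:
            t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d2 = ((points - proj) ** 2).sum(axis=1)
        on |= d2 <= tol * tol
    return on


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

def _default_tiling():
    from .tiling import TilingConfig

    return TilingConfig()


def _default_arch():
    from .unet import ArchitectureSpec

    return ArchitectureSpec()


def _default_training():
    from .training import TrainingConfig

    return TrainingConfig()


def _default_postprocess():
    from .postprocess import PostprocessConfig

    return PostprocessConfig()


@dataclass
class PipelineConfig:
    """Aggregate configuration for all pipeline stages.

    Defaults are the method's published operating point: 320 px tiles with
    5% overlap; a 3-level UNet with (10, 20, 30) filters of size 5x5 and
    stride-2 down-sampling; a 90/10 train/validation split with
    augmentation of half the data; and post-processing thresholds of 5
    slices, 15 px centroid shift and 100 voxels.
    """

    tiling: "TilingConfig" = field(default_factory=_default_tiling)
    model: "ArchitectureSpec" = field(default_factory=_default_arch)
    training: "TrainingConfig" = field(default_factory=_default_training)
    postprocess: "PostprocessConfig" = field(default_factory=_default_postprocess)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.postprocess.min_slices < 1 or self.postprocess.min_size < 1:
            raise ValueError("post-processing thresholds must be strictly positive")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from defaults, a YAML file and overrides.

    The YAML file (and the ``overrides`` mapping) hold flat sections named
    after the stages (``tiling``, ``model``, ``training``, ``postprocess``)
    plus a top-level ``seed``.  Every key deviating from the default is
    echoed to the log.
    """
    cfg = PipelineConfig()
    layers: list[dict] = []
    if path is not None:
        with open(path) as fh:
            layers.append(yaml.safe_load(fh) or {})
    if overrides:
        layers.append(overrides)
    for layer in layers:
        for section, values in layer.items():
            if section == "seed":
                logger.info("config override: seed=%r", values)
                cfg.seed = int(values)
                continue
            target = getattr(cfg, section, None)
            if target is None or not dataclasses.is_dataclass(target):
                raise KeyError(f"unknown config section {section!r}")
            for key, value in (values or {}).items():
                if not hasattr(target, key):
                    raise KeyError(f"unknown config key {section}.{key}")
                if isinstance(value, list):
                    value = tuple(value)
                logger.info("config override: %s.%s=%r", section, key, value)
                setattr(target, key, value)
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Flatten a PipelineConfig into plain nested dicts (for manifests)."""
    return dataclasses.asdict(cfg)
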