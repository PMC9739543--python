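"""A reduced UNet for per-slice semantic segmentation of axonal blebs.

Architecture
------------
The down-sampling arm has three convolutional layers with 5x5 filters of
sequentially increasing count (10, 20, 30), each performed with a stride of
two so that down-sampling happens in the convolution itself (no separate
pooling).  The up-sampling arm mirrors it with 5x5 stride-2 transposed
convolutions of decreasing filter count (30, 20, 10), each followed by
concatenation with the same-resolution down-arm feature map (the skip at
full resolution is the input itself).  A final 1x1 convolution with softmax
produces a two-channel categorical output (background, bleb) that is
thresholded at 0.5 for a binary segmentation.

All convolutions use "same" padding so the output map matches the input
tile; rectified-linear activations follow every convolution except the
head.  Inputs must have a side divisible by 2^3 = 8 (the default 320 px
tile gives 320 -> 160 -> 80 -> 40).

The network is implemented directly on numpy arrays: convolution via
strided sliding windows, transposed convolution as the exact adjoint of the
strided convolution, and analytic gradients for training.  At this size
(~100k parameters) a CPU forward/backward pass is fast enough for both
training and inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tiling import TilingConfig, extract_tiles, plan_tiles, stitch_tiles

__all__ = [
    "ArchitectureSpec",
    "UNet2D",
    "build_network",
    "predict_tile",
    "binarize",
    "predict_stack",
    "normalize_tile",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ArchitectureSpec:
    down_filters: tuple[int, ...] = (10, 20, 30)
    up_filters: tuple[int, ...] = (30, 20, 10)
    kernel_size: int = 5
    stride: int = 2
    in_channels: int = 1
    n_classes: int = 2
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if tuple(self.up_filters) != tuple(reversed(self.down_filters)):
            raise ValueError("up-arm filters must mirror the down arm")
        if self.n_classes != 2:
            raise ValueError("the head is a two-channel categorical output")

    @property
    def depth(self) -> int:
        return len(self.down_filters)

    @property
    def side_multiple(self) -> int:
        return self.stride ** self.depth


# ---------------------------------------------------------------------------
# convolution primitives (stride-s "same" conv and its exact adjoint)
# ---------------------------------------------------------------------------

def _same_pads(size: int, k: int, s: int) -> tuple[int, int]:
    out = -(-size // s)
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, s: int):
    """y[n,f] = sum_c x[n,c] * w[f,c]  (stride s, 'same' padding)."""
    k = w.shape[2]
    _, _, h, wd = x.shape
    (pt, pb), (pl, pr) = _same_pads(h, k, s), _same_pads(wd, k, s)
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    y = np.einsum("nchwkl,fckl->nfhw", win, w, optimize=True)
    y += b[:, None, None]
    return y, (xp, win, (pt, pb, pl, pr), x.shape)


def _conv_backward(dy: np.ndarray, w: np.ndarray, cache, s: int):
    xp, win, (pt, pb, pl, pr), x_shape = cache
    k = w.shape[2]
    dw = np.einsum("nfhw,nchwkl->fckl", dy, win, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    dxp = np.zeros_like(xp)
    ho, wo = dy.shape[2], dy.shape[3]
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += np.einsum(
                "nfhw,fc->nchw", dy, w[:, :, ki, kj], optimize=True
            )
    h, wd = x_shape[2], x_shape[3]
    dx = dxp[:, :, pt : pt + h, pl : pl + wd]
    return dx, dw, db


def _tconv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, s: int):
    """Stride-s transposed convolution: the adjoint of `_conv_forward`.

    ``w`` has shape (in_channels, out_channels, k, k); the output spatial
    size is exactly ``s`` times the input's.
    """
    k = w.shape[2]
    n, c, h, wd = x.shape
    f = w.shape[1]
    ho, wo = h * s, wd * s
    (pt, pb), (pl, pr) = _same_pads(ho, k, s), _same_pads(wo, k, s)
    yp = np.zeros((n, f, ho + pt + pb, wo + pl + pr), dtype=x.dtype)
    for ki in range(k):
        for kj in range(k):
            yp[:, :, ki : ki + s * h : s, kj : kj + s * wd : s] += np.einsum(
                "nchw,cf->nfhw", x, w[:, :, ki, kj], optimize=True
            )
    y = yp[:, :, pt : pt + ho, pl : pl + wo].copy()
    y += b[:, None, None]
    return y, (x, (ho, wo), (pt, pb, pl, pr))


def _tconv_backward(dy: np.ndarray, w: np.ndarray, cache, s: int):
    x, (ho, wo), (pt, pb, pl, pr) = cache
    k = w.shape[2]
    dyp = np.pad(dy, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = sliding_window_view(dyp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    dx = np.einsum("nfhwkl,cfkl->nchw", win, w, optimize=True)
    dw = np.einsum("nchw,nfhwkl->cfkl", x, win, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    return dx, dw, db


def _softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class UNet2D:
    """Reduced UNet; parameters live in ``self.params`` as a flat dict."""

    def __init__(self, spec: ArchitectureSpec | None = None, seed: int = 0):
        self.spec = spec or ArchitectureSpec()
        rng = np.random.default_rng(seed)
        k = self.spec.kernel_size
        self.params: dict[str, np.ndarray] = {}

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        # down arm
        c_in = self.spec.in_channels
        self._down_channels = [c_in]
        for i, f in enumerate(self.spec.down_filters):
            self.params[f"down{i}_w"] = he((f, c_in, k, k), c_in * k * k)
            self.params[f"down{i}_b"] = np.zeros(f)
            c_in = f
            self._down_channels.append(f)
        # up arm: tconv then concat with the same-resolution down feature
        self._cat_channels = []
        for i, f in enumerate(self.spec.up_filters):
            self.params[f"up{i}_w"] = he((c_in, f, k, k), c_in * k * k)
            self.params[f"up{i}_b"] = np.zeros(f)
            skip = self._down_channels[self.spec.depth - 1 - i]
            c_in = f + skip
            self._cat_channels.append(c_in)
        self.params["head_w"] = he(
            (self.spec.n_classes, c_in, 1, 1), c_in
        )
        self.params["head_b"] = np.zeros(self.spec.n_classes)

    # -- introspection -----------------------------------------------------
    def describe(self) -> dict:
        s = self.spec
        return {
            "n_down_layers": s.depth,
            "n_up_layers": len(s.up_filters),
            "down_filters": tuple(s.down_filters),
            "up_filters": tuple(s.up_filters),
            "kernel_size": s.kernel_size,
            "stride": s.stride,
            "head": "1x1 conv + softmax",
            "n_output_channels": s.n_classes,
            "threshold": s.threshold,
            "n_parameters": int(sum(p.size for p in self.params.values())),
        }

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (N, 1, H, W) normalized floats -> softmax probs (N, 2, H, W)."""
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ValueError(f"expected (N, {self.spec.in_channels}, H, W), got {x.shape}")
        m = self.spec.side_multiple
        if x.shape[2] % m or x.shape[3] % m:
            raise ValueError(f"input sides must be divisible by {m}, got {x.shape[2:]}")
        s = self.spec.stride
        caches: dict = {"skips": [x]}
        h = x.astype(np.float64, copy=False)
        # down arm
        for i in range(self.spec.depth):
            z, cc = _conv_forward(h, self.params[f"down{i}_w"], self.params[f"down{i}_b"], s)
            h = np.maximum(z, 0.0)
            caches[f"down{i}"] = (cc, z > 0)
            if i < self.spec.depth - 1:
                caches["skips"].append(h)
        skips = caches["skips"]
        # up arm with skip concatenation
        for i in range(len(self.spec.up_filters)):
            z, cc = _tconv_forward(h, self.params[f"up{i}_w"], self.params[f"up{i}_b"], s)
            u = np.maximum(z, 0.0)
            caches[f"up{i}"] = (cc, z > 0, u.shape[1])
            h = np.concatenate([u, skips[self.spec.depth - 1 - i]], axis=1)
        logits, cc = _conv_forward(h, self.params["head_w"], self.params["head_b"], 1)
        caches["head"] = cc
        probs = _softmax(logits)
        if want_cache:
            return probs, caches
        return probs

    def backward(self, caches: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every parameter, given dL/dlogits."""
        grads: dict[str, np.ndarray] = {}
        s = self.spec.stride
        dh, grads["head_w"], grads["head_b"] = _conv_backward(
            dlogits, self.params["head_w"], caches["head"], 1
        )
        dskips = [None] * self.spec.depth  # gradient flowing into each skip
        for i in reversed(range(len(self.spec.up_filters))):
            cc, relu_mask, n_up = caches[f"up{i}"]
            du, dskip = dh[:, :n_up], dh[:, n_up:]
            dskips[self.spec.depth - 1 - i] = dskip
            dz = du * relu_mask
            dh, grads[f"up{i}_w"], grads[f"up{i}_b"] = _tconv_backward(
                dz, self.params[f"up{i}_w"], cc, s
            )
        for i in reversed(range(self.spec.depth)):
            cc, relu_mask = caches[f"down{i}"]
            if i < self.spec.depth - 1:
                dh = dh + dskips[i + 1]
            dz = dh * relu_mask
            dh, grads[f"down{i}_w"], grads[f"down{i}_b"] = _conv_backward(
                dz, self.params[f"down{i}_w"], cc, s
            )
        return grads


def build_network(spec: ArchitectureSpec | None = None, seed: int = 0) -> UNet2D:
    """Construct a seeded reduced UNet."""
    return UNet2D(spec, seed=seed)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def normalize_tile(tile: np.ndarray) -> np.ndarray:
    """Scale intensities to [0, 1]: integer inputs by their dtype maximum,
    float inputs are assumed already unit-scaled."""
    if np.issubdtype(tile.dtype, np.integer):
        return tile.astype(np.float64) / float(np.iinfo(tile.dtype).max)
    return tile.astype(np.float64)


def predict_tile(network: UNet2D, tile: np.ndarray) -> np.ndarray:
    """Segment one normalized side x side tile.

    Returns a (2, H, W) probability map with channels (background, bleb);
    channels sum to 1 at every pixel.
    """
    if tile.ndim != 2:
        raise ValueError(f"expected a 2D tile, got shape {tile.shape}")
    probs = network.forward(tile[np.newaxis, np.newaxis].astype(np.float64))
    return probs[0]


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold the bleb-channel probability; ties (== threshold) are
    foreground.  Accepts a (2, H, W) two-channel map or an (H, W)
    bleb-probability map."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    bleb = prob_map[1] if prob_map.ndim == 3 else prob_map
    return (bleb >= threshold).astype(np.uint8)


def predict_stack(
    network: UNet2D,
    stack: np.ndarray,
    tiling_config: TilingConfig | None = None,
    threshold: float | None = None,
) -> np.ndarray:
    """Segment a whole (z, y, x) stack slice by slice.

    Each slice is tiled, every tile normalized and predicted, the
    bleb-channel maps stitched (per-pixel max over overlaps), and the
    result binarized.  Output is a binary stack of the input shape; any
    z >= 1 is accepted.
    """
    if stack.ndim != 3:
        raise ValueError(f"expected a (z, y, x) stack, got shape {stack.shape}")
    tiling_config = tiling_config or TilingConfig()
    if tiling_config.tile_side % network.spec.side_multiple:
        raise ValueError(
            f"tile side {tiling_config.tile_side} not divisible by "
            f"{network.spec.side_multiple}"
        )
    thr = network.spec.threshold if threshold is None else threshold
    out = np.zeros(stack.shape, dtype=np.uint8)
    for z in range(stack.shape[0]):
        grid = plan_tiles(stack.shape[1:], tiling_config)
        tiles = extract_tiles(stack[z], grid)
        batch = np.stack([normalize_tile(t) for t in tiles])[:, np.newaxis]
        probs = network.forward(batch)
        bleb_maps = [probs[i, 1] for i in range(len(tiles))]
        stitched = stitch_tiles(bleb_maps, grid)
        out[z] = binarize(stitched, thr)
    return out


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(network: UNet2D, path: str | Path) -> None:
    import dataclasses

    spec_json = json.dumps(dataclasses.asdict(network.spec))
    with open(path, "wb") as fh:
        np.savez(fh, _spec=np.frombuffer(spec_json.encode(), dtype=np.uint8),
                 **network.params)


def load_checkpoint(path: str | Path) -> UNet2D:
    with np.load(Path(path)) as data:
        spec_dict = json.loads(bytes(data["_spec"]).decode())
        for key in ("down_filters", "up_filters"):
            spec_dict[key] = tuple(spec_dict[key])
        net = UNet2D(ArchitectureSpec(**spec_dict), seed=0)
        net.set_params({k: data[k] for k in net.params})
    return net
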