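"""Training the segmentation network.

Tiles are sorted randomly into training (90%) and validation (10%) groups.
The loss is per-pixel categorical cross-entropy with "spatial weighting":
each pixel's contribution is

    w(p) = w_class(p) + w0 * exp(-(d1(p) + d2(p))^2 / (2 sigma^2))

where ``d1`` and ``d2`` are the distances from the pixel to its nearest
and second-nearest annotated object.  The boost term is largest in narrow
gaps between nearby objects, sharpening object borders; with fewer than
two objects it vanishes, leaving pure class-balance weights.

Cross-entropy loss and the Jaccard index between the binarized output and
the ground truth are logged every epoch; training stops at the configured
step budget or once validation loss has risen for ``patience`` consecutive
epochs (the classic overfitting signal), restoring the best-validation
parameters.  Optimization uses Adam.  Augmentation (when enabled) is
applied to an exact fraction of the training items, re-sampled each epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .unet import UNet2D, binarize

__all__ = [
    "TrainingConfig",
    "TrainingLog",
    "EpochRecord",
    "split_dataset",
    "make_weight_map",
    "weighted_cross_entropy",
    "jaccard_index",
    "EarlyStopper",
    "train",
]

_EPS = 1e-7  # probability clipping floor


@dataclass
class TrainingConfig:
    train_fraction: float = 0.90
    max_epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    augment_fraction: float = 0.50
    patience: int = 3
    seed: int = 0
    # spatial weighting
    w0: float = 10.0
    sigma: float = 5.0
    class_weights: tuple[float, float] = (1.0, 5.0)  # (background, bleb)

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    @property
    def validation_fraction(self) -> float:
        return 1.0 - self.train_fraction


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    val_ji: float


@dataclass
class TrainingLog:
    records: list[EpochRecord] = field(default_factory=list)
    stopped_epoch: int = 0
    stop_reason: str = ""
    best_epoch: int = 0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "epoch": r.epoch,
                    "train_loss": r.train_loss,
                    "val_loss": r.val_loss,
                    "val_ji": r.val_ji,
                }
                for r in self.records
            ]
        )


# ---------------------------------------------------------------------------
# data handling
# ---------------------------------------------------------------------------

def split_dataset(items: Sequence, train_fraction: float = 0.90, seed: int = 0):
    """Randomly partition items into (train, validation) groups.

    ``|train| = round(train_fraction * n)``; the partition is disjoint and
    exhaustive, with order given by a seeded shuffle.
    """
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    n_train = int(round(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train_fraction={train_fraction} yields an empty partition for n={n}"
        )
    order = np.random.default_rng(seed).permutation(n)
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train:]]
    return train, val


# ---------------------------------------------------------------------------
# spatial weighting and metrics
# ---------------------------------------------------------------------------

def make_weight_map(
    truth_mask: np.ndarray,
    w0: float = 10.0,
    sigma: float = 5.0,
    class_weights: tuple[float, float] = (1.0, 5.0),
) -> np.ndarray:
    """Per-pixel loss weights: class balance plus a border boost.

    The boost ``w0 * exp(-(d1 + d2)^2 / (2 sigma^2))`` uses the distances
    to the nearest and second-nearest connected objects of the mask; it
    needs at least two objects and decays to zero away from them.  All
    weights are strictly positive.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    mask = np.asarray(truth_mask) > 0
    if mask.ndim != 2:
        raise ValueError("weight maps are per-slice (2D)")
    w_bg, w_fg = class_weights
    weights = np.where(mask, w_fg, w_bg).astype(np.float64)
    if w0 == 0.0:
        return weights
    labels, n_obj = ndimage.label(mask)
    if n_obj >= 2:
        dists = np.stack(
            [
                ndimage.distance_transform_edt(labels != i)
                for i in range(1, n_obj + 1)
            ]
        )
        dists.sort(axis=0)
        d1, d2 = dists[0], dists[1]
        weights += w0 * np.exp(-((d1 + d2) ** 2) / (2.0 * sigma**2))
    return weights


def weighted_cross_entropy(
    prob_map: np.ndarray, truth_mask: np.ndarray, weight_map: np.ndarray | None = None
) -> float:
    """Mean over pixels of ``weight * (-log p_true_class)``.

    ``prob_map`` is (2, H, W); probabilities are clipped at 1e-7.  Uniform
    unit weights reduce this to plain categorical cross-entropy.
    """
    truth = np.asarray(truth_mask)
    if prob_map.shape[1:] != truth.shape:
        raise ValueError(
            f"probability map {prob_map.shape} does not match mask {truth.shape}"
        )
    p_true = np.where(truth > 0, prob_map[1], prob_map[0])
    nll = -np.log(np.clip(p_true, _EPS, 1.0))
    if weight_map is None:
        return float(nll.mean())
    if weight_map.shape != truth.shape:
        raise ValueError("weight map shape mismatch")
    return float((weight_map * nll).mean())


def jaccard_index(bin_a: np.ndarray, bin_b: np.ndarray) -> float:
    """|A ∩ B| / |A ∪ B| for binary maps; 1.0 when both are empty."""
    a = np.asarray(bin_a) > 0
    b = np.asarray(bin_b) > 0
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


# ---------------------------------------------------------------------------
# early stopping
# ---------------------------------------------------------------------------

class EarlyStopper:
    """Stop after ``patience`` consecutive epochs of rising validation loss,
    remembering the best (lowest validation loss) epoch."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self._prev = np.inf
        self._rising = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record this epoch's validation loss; return True to stop."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
        self._rising = self._rising + 1 if val_loss > self._prev else 0
        self._prev = val_loss
        return self._rising >= self.patience


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _batch_loss_and_grad(net: UNet2D, images: np.ndarray, masks: np.ndarray,
                         weights: np.ndarray):
    """Weighted cross-entropy over a batch and dL/dparams."""
    probs, caches = net.forward(images, want_cache=True)
    onehot = np.stack([(masks == 0), (masks > 0)], axis=1).astype(np.float64)
    p_true = np.where(masks > 0, probs[:, 1], probs[:, 0])
    nll = -np.log(np.clip(p_true, _EPS, 1.0))
    n_pix = nll.size
    loss = float((weights * nll).sum() / n_pix)
    # d loss / d logits of the softmax cross-entropy, per-pixel weighted
    dlogits = (probs - onehot) * weights[:, None] / n_pix
    grads = net.backward(caches, dlogits)
    return loss, grads


def _evaluate(net: UNet2D, items, cfg: TrainingConfig):
    """Mean weighted loss and mean Jaccard index over a set of tiles."""
    losses, jis = [], []
    for img, mask in items:
        probs = net.forward(img[np.newaxis, np.newaxis])[0]
        wmap = make_weight_map(mask, cfg.w0, cfg.sigma, cfg.class_weights)
        losses.append(weighted_cross_entropy(probs, mask, wmap))
        jis.append(jaccard_index(binarize(probs, net.spec.threshold), mask))
    return float(np.mean(losses)), float(np.mean(jis))


def train(
    network: UNet2D,
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    config: TrainingConfig | None = None,
) -> tuple[UNet2D, TrainingLog]:
    """Train on (normalized image tile, binary mask tile) pairs.

    The dataset is split into train/validation groups by the configured
    fraction; the configured fraction of training items is augmented anew
    each epoch.  Returns the network restored to its best-validation
    parameters together with the per-epoch log.
    """
    from .scenes import augment, select_augmented

    cfg = config or TrainingConfig()
    rng = np.random.default_rng(cfg.seed)
    train_items, val_items = split_dataset(dataset, cfg.train_fraction, cfg.seed)
    if not train_items or not val_items:
        raise ValueError("empty train or validation partition")

    weight_cache = {
        id(mask): make_weight_map(mask, cfg.w0, cfg.sigma, cfg.class_weights)
        for _, mask in train_items
    }
    opt = _Adam(network.params, cfg.learning_rate)
    stopper = EarlyStopper(cfg.patience)
    log = TrainingLog()
    best_params = network.copy_params()
    # epoch-0 baseline: metrics of the untrained network, so the log shows
    # learning relative to initialization
    train_loss0, _ = _evaluate(network, train_items, cfg)
    val_loss0, val_ji0 = _evaluate(network, val_items, cfg)
    log.records.append(EpochRecord(0, train_loss0, val_loss0, val_ji0))
    stopper.update(0, val_loss0)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_items))
        aug_sel = set(
            select_augmented(
                len(train_items), cfg.augment_fraction, int(rng.integers(2**31))
            )
        )
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            imgs, msks, wmaps = [], [], []
            for i in idx:
                img, mask = train_items[i]
                if i in aug_sel:
                    img, mask = augment(img, mask, int(rng.integers(2**31)))
                    wmap = make_weight_map(mask, cfg.w0, cfg.sigma, cfg.class_weights)
                else:
                    wmap = weight_cache[id(train_items[i][1])]
                imgs.append(img)
                msks.append(mask)
                wmaps.append(wmap)
            loss, grads = _batch_loss_and_grad(
                network,
                np.stack(imgs)[:, np.newaxis],
                np.stack(msks),
                np.stack(wmaps),
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (non-finite loss)"
                )
            opt.step(network.params, grads)
            epoch_losses.append(loss)
        val_loss, val_ji = _evaluate(network, val_items, cfg)
        log.records.append(
            EpochRecord(epoch, float(np.mean(epoch_losses)), val_loss, val_ji)
        )
        stop = stopper.update(epoch, val_loss)
        if stopper.best_epoch == epoch:
            best_params = network.copy_params()
        if stop:
            log.stop_reason = (
                f"validation loss rose for {cfg.patience} consecutive epochs"
            )
            break
    else:
        log.stop_reason = "reached max_epochs"
    log.stopped_epoch = log.records[-1].epoch
    log.best_epoch = stopper.best_epoch
    network.set_params(best_params)
    return network, log
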