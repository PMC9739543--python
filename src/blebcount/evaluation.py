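"""Object-level agreement between two segmentations.

Catalogs of 3D objects (machine vs human, or machine vs planted truth) are
matched one-to-one, greedily by descending voxel overlap with a stable
object-id tie-break; a pair matches when it shares at least one voxel (a
minimum intersection-over-union can be required instead via
``min_iou``).  From the resulting confusion counts:

    PPV         = TP / (TP + FP)        (positive predictive value)
    sensitivity = TP / (TP + FN)
    F1          = harmonic mean of PPV and sensitivity

Zero-denominator cases return 0 so reports stay total.  A pixel-level
Jaccard index over the survivor masks is reported alongside the
object-level metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .postprocess import BlebCatalog, BlebObject
from .training import jaccard_index

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "match_objects",
    "compute_metrics",
    "evaluate_catalogs",
    "compare_counts",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class EvalReport:
    counts: ConfusionCounts
    ppv: float
    sensitivity: float
    f1: float
    n_predicted: int
    n_reference: int
    pixel_jaccard: float | None = None

    def to_dict(self) -> dict:
        d = {
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "ppv": self.ppv,
            "sensitivity": self.sensitivity,
            "f1": self.f1,
            "n_predicted": self.n_predicted,
            "n_reference": self.n_reference,
        }
        if self.pixel_jaccard is not None:
            d["pixel_jaccard"] = self.pixel_jaccard
        return d


def _overlap(a: BlebObject, b: BlebObject) -> int:
    return len(np.intersect1d(a.voxel_index, b.voxel_index, assume_unique=True))


def match_objects(
    predicted: Sequence[BlebObject] | BlebCatalog,
    reference: Sequence[BlebObject] | BlebCatalog,
    min_iou: float = 0.0,
) -> ConfusionCounts:
    """Greedy one-to-one matching of predicted to reference objects.

    Candidate pairs (>= 1 shared voxel and IoU >= ``min_iou``) are taken in
    order of descending overlap, ties broken by (predicted id, reference
    id).  TP = matched pairs, FP = unmatched predicted, FN = unmatched
    reference.
    """
    pred = predicted.objects if isinstance(predicted, BlebCatalog) else list(predicted)
    ref = reference.objects if isinstance(reference, BlebCatalog) else list(reference)
    if pred and ref and pred[0].shape != ref[0].shape:
        raise ValueError(
            f"catalog geometries differ: {pred[0].shape} vs {ref[0].shape}"
        )
    pairs = []
    for i, p in enumerate(pred):
        for j, r in enumerate(ref):
            ov = _overlap(p, r)
            if ov < 1:
                continue
            union = p.voxel_count + r.voxel_count - ov
            if ov / union >= min_iou:
                pairs.append((ov, i, j))
    pairs.sort(key=lambda t: (-t[0], pred[t[1]].id, ref[t[2]].id))
    used_p: set[int] = set()
    used_r: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_p or j in used_r:
            continue
        used_p.add(i)
        used_r.add(j)
        tp += 1
    return ConfusionCounts(tp=tp, fp=len(pred) - tp, fn=len(ref) - tp)


def compute_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(PPV, sensitivity, F1) from object-level confusion counts; any
    zero-denominator metric is 0."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    ppv = tp / (tp + fp) if tp + fp else 0.0
    sens = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * ppv * sens / (ppv + sens) if ppv + sens else 0.0
    return ppv, sens, f1


def evaluate_catalogs(
    predicted: BlebCatalog,
    reference: BlebCatalog,
    min_iou: float = 0.0,
    with_pixel_jaccard: bool = True,
) -> EvalReport:
    """Full object-level report for two catalogs over the same stack."""
    counts = match_objects(predicted, reference, min_iou=min_iou)
    ppv, sens, f1 = compute_metrics(counts)
    pj = None
    if with_pixel_jaccard and predicted.shape and reference.shape:
        pj = jaccard_index(predicted.survivor_mask(), reference.survivor_mask())
    return EvalReport(
        counts=counts,
        ppv=ppv,
        sensitivity=sens,
        f1=f1,
        n_predicted=counts.tp + counts.fp,
        n_reference=counts.tp + counts.fn,
        pixel_jaccard=pj,
    )


def compare_counts(counts_by_rater: Mapping[str, Mapping[str, int | BlebCatalog]]):
    """Per-nerve total bleb counts for >= 2 raters, with pairwise
    differences.

    ``counts_by_rater[rater][nerve]`` is a count or a catalog.  Returns a
    tidy DataFrame with one row per (nerve, rater pair): both counts, the
    absolute difference, and the relative difference (fraction of the
    smaller count; 0 when both are 0).
    """
    import pandas as pd

    raters = list(counts_by_rater)
    if len(raters) < 2:
        raise ValueError("need at least two raters")
    nerves = set(counts_by_rater[raters[0]])
    for r in raters[1:]:
        if set(counts_by_rater[r]) != nerves:
            raise ValueError("raters must cover the same nerves")

    def as_count(v):
        return v.count if isinstance(v, BlebCatalog) else int(v)

    rows = []
    for nerve in sorted(nerves):
        for a_idx, ra in enumerate(raters):
            for rb in raters[a_idx + 1 :]:
                ca = as_count(counts_by_rater[ra][nerve])
                cb = as_count(counts_by_rater[rb][nerve])
                lo = min(ca, cb)
                rows.append(
                    {
                        "nerve": nerve,
                        "rater_a": ra,
                        "rater_b": rb,
                        "count_a": ca,
                        "count_b": cb,
                        "abs_diff": abs(ca - cb),
                        "rel_diff": abs(ca - cb) / lo if lo else 0.0,
                    }
                )
    return pd.DataFrame(rows)
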