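"""Dice coefficient and intersection-over-union for binary segmentations.

Dice = 2|G ∩ P| / (|G| + |P|), IoU = |G ∩ P| / |G ∪ P|; both in [0, 1] and
related by Dice = 2·IoU / (1 + IoU).  When both masks are empty there is
nothing to disagree about, so both metrics return 1 (with a warning); an
empty mask against a non-empty one scores 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from gastroseg.phantoms import MaskPair

__all__ = ["MetricReport", "dice", "iou", "evaluate_set"]


@dataclass(frozen=True)
class MetricReport:
    """Overlap metrics plus the raw pixel counts behind them."""

    dice: float
    iou: float
    n_gt: int
    n_pred: int
    n_intersection: int
    n_union: int


def _validate(gt: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    for name, arr in (("gt", gt), ("pred", pred)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(
                f"{name} mask is not binary; threshold soft predictions first "
                "(e.g. phi >= 0.5)"
            )
    return gt.astype(bool), pred.astype(bool)


def report(gt: np.ndarray, pred: np.ndarray) -> MetricReport:
    """Full MetricReport for one binary mask pair."""
    g, p = _validate(gt, pred)
    n_g, n_p = int(g.sum()), int(p.sum())
    n_i = int((g & p).sum())
    n_u = int((g | p).sum())
    if n_g == 0 and n_p == 0:
        warnings.warn("both masks empty; returning dice = iou = 1", stacklevel=2)
        return MetricReport(1.0, 1.0, 0, 0, 0, 0)
    d = 2.0 * n_i / (n_g + n_p)
    j = n_i / n_u
    return MetricReport(d, j, n_g, n_p, n_i, n_u)


def dice(gt: np.ndarray, pred: np.ndarray) -> float:
    """Dice coefficient 2|G∩P|/(|G|+|P|) of two binary masks."""
    return report(gt, pred).dice


def iou(gt: np.ndarray, pred: np.ndarray) -> float:
    """Intersection over union |G∩P|/|G∪P| of two binary masks."""
    return report(gt, pred).iou


def evaluate_set(
    pairs: Sequence[MaskPair], threshold: float = 0.5
) -> tuple[list[MetricReport], MetricReport]:
    """Per-image reports plus their unweighted mean for a set of mask pairs.

    Soft predictions are binarized at ``threshold`` first.  The mean report
    averages dice/iou arithmetically over images and sums the counts.
    """
    if len(pairs) == 0:
        raise ValueError("cannot evaluate an empty list of mask pairs")
    reports = []
    for mp in pairs:
        if mp.predicted is None:
            raise ValueError("MaskPair has no prediction to evaluate")
        pred = (np.asarray(mp.predicted) >= threshold).astype(np.uint8)
        reports.append(report(mp.ground_truth, pred))
    mean = MetricReport(
        dice=float(np.mean([r.dice for r in reports])),
        iou=float(np.mean([r.iou for r in reports])),
        n_gt=sum(r.n_gt for r in reports),
        n_pred=sum(r.n_pred for r in reports),
        n_intersection=sum(r.n_intersection for r in reports),
        n_union=sum(r.n_union for r in reports),
    )
    return reports, mean
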