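"""Segmentation and ranking metrics: Dice, IoU, precision, recall, pixel AUC.

Conventions for degenerate masks: if both prediction and truth are empty the
overlap metrics are 1 (perfect agreement); if exactly one is empty they are 0.
AUC uses the Mann-Whitney formulation (ties averaged) over the per-pixel
anomaly scores and is undefined when the truth contains a single class.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "SegScores",
    "confusion_counts",
    "seg_scores",
    "pixel_auc",
    "aggregate",
    "equidistant_slices",
]


@dataclasses.dataclass(frozen=True)
class SegScores:
    dice: float
    iou: float
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    tn: int
    auc: float | None = None

    def as_dict(self) -> dict:
        d = {"dice": self.dice, "iou": self.iou, "precision": self.precision,
             "recall": self.recall}
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def _bool_mask(m) -> np.ndarray:
    return np.asarray(m).astype(bool)


def confusion_counts(pred, truth) -> tuple[int, int, int, int]:
    """Pixel-level (tp, fp, fn, tn); the four always sum to H*W."""
    p = _bool_mask(pred)
    t = _bool_mask(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return tp, fp, fn, tn


def seg_scores(pred, truth) -> SegScores:
    """Dice, IoU, precision and recall between two binary masks."""
    tp, fp, fn, tn = confusion_counts(pred, truth)
    if tp + fp + fn == 0:  # both masks empty: perfect agreement
        return SegScores(1.0, 1.0, 1.0, 1.0, tp, fp, fn, tn)
    dice = 2.0 * tp / (2.0 * tp + fp + fn)
    iou = tp / (tp + fp + fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return SegScores(dice, iou, precision, recall, tp, fp, fn, tn)


def pixel_auc(scores, truth) -> float:
    """Area under the ROC curve of the anomaly scores as a pixel ranking.

    Mann-Whitney U with averaged ties:
    AUC = (mean rank of anomalous pixels - (n1+1)/2) / n0.
    """
    s = np.asarray(scores, dtype=np.float64).ravel()
    t = _bool_mask(truth).ravel()
    if s.shape != t.shape:
        raise ValueError("scores and truth must share a shape")
    n1 = int(t.sum())
    n0 = t.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("pixel AUC undefined: ground truth has a single class")
    ranks = rankdata(s)
    return float((ranks[t].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def aggregate(scores: list) -> dict:
    """Per-metric mean and population standard deviation over slices.

    Accepts a list of :class:`SegScores` or of plain dicts; returns
    ``{metric: (mean, std)}``.
    """
    if not scores:
        raise ValueError("no scores to aggregate")
    dicts = [s.as_dict() if isinstance(s, SegScores) else dict(s) for s in scores]
    keys = dicts[0].keys()
    out = {}
    for key in keys:
        vals = np.array([d[key] for d in dicts], dtype=np.float64)
        out[key] = (float(vals.mean()), float(vals.std()))
    return out


def equidistant_slices(lo: int, hi: int, k: int = 4) -> list[int]:
    """k equidistant slice indices spanning the inclusive range [lo, hi]."""
    if hi < lo:
        raise ValueError(f"empty slice range [{lo}, {hi}]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return [int(round(v)) for v in np.linspace(lo, hi, k)]
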