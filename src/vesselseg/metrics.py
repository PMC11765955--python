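"""Segmentation evaluation: Dice, precision, recall, and summary statistics.

The Dice similarity coefficient DSC = 2|X∩Y| / (|X|+|Y|) = 2TP/(2TP+FP+FN)
measures overlap between a predicted mask X and a ground-truth mask Y.
Conventions for degenerate cases: two empty masks score 1.0 (a correctly
predicted vessel-free image is a perfect prediction), exactly one empty
mask scores 0.0; precision/recall with a zero denominator score 0.0.

``compare_annotation_rounds`` reproduces the intra-observer study design:
a prediction is scored against an earlier annotation round ("old") and a
repeat round ("new"), and the two human rounds are scored against each
other ("human"), each series summarized by mean/min/max and quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "SummaryStats",
    "confusion",
    "dice",
    "precision_recall",
    "summarize",
    "compare_annotation_rounds",
    "score_pair",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SummaryStats:
    average: float
    minimum: float
    maximum: float
    p25: float
    p50: float
    p75: float


def _as_bool(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-level confusion counts of a predicted mask against the truth."""
    pred, truth = _as_bool(pred, truth)
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=pred.size - tp - fp - fn)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity coefficient 2|X∩Y|/(|X|+|Y|)."""
    pred, truth = _as_bool(pred, truth)
    nx = int(np.count_nonzero(pred))
    ny = int(np.count_nonzero(truth))
    if nx == 0 and ny == 0:
        return 1.0
    return 2.0 * np.count_nonzero(pred & truth) / (nx + ny)


def precision_recall(c: ConfusionCounts) -> tuple[float, float]:
    """Precision tp/(tp+fp) and recall tp/(tp+fn); 0.0 on zero denominators."""
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    return precision, recall


def score_pair(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Dice, precision, and recall for one mask pair."""
    c = confusion(pred, truth)
    p, r = precision_recall(c)
    return {"dice": dice(pred, truth), "precision": p, "recall": r}


def summarize(scores: Sequence[float] | Iterable[float]) -> SummaryStats:
    """Mean, min, max, and linear-interpolation quartiles of a score list."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty score list")
    q25, q50, q75 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return SummaryStats(
        average=float(arr.mean()),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        p25=float(q25),
        p50=float(q50),
        p75=float(q75),
    )


def compare_annotation_rounds(
    masks_a: Mapping[str, np.ndarray],
    masks_b: Mapping[str, np.ndarray],
    preds: Mapping[str, np.ndarray],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score predictions against two annotation rounds and the rounds against each other.

    Parameters
    ----------
    masks_a, masks_b
        Earlier ("old") and repeat ("new") annotation rounds, keyed by
        image id.
    preds
        Predicted masks, same ids.

    Returns
    -------
    scores : DataFrame with columns comparison, image_id, dice
        One row per (comparison, image); comparisons are "old" (pred vs a),
        "new" (pred vs b), "human" (a vs b).
    summary : DataFrame indexed by comparison
        Columns average, minimum, maximum, p25, p50, p75.
    """
    ids = sorted(masks_a)
    if sorted(masks_b) != ids or sorted(preds) != ids:
        raise ValueError("mask sets must share the same image ids")
    rows = []
    for image_id in ids:
        rows.append(("old", image_id, dice(preds[image_id], masks_a[image_id])))
        rows.append(("new", image_id, dice(preds[image_id], masks_b[image_id])))
        rows.append(("human", image_id, dice(masks_a[image_id], masks_b[image_id])))
    scores = pd.DataFrame(rows, columns=["comparison", "image_id", "dice"])
    summary = pd.DataFrame(
        {
            comp: vars(summarize(grp["dice"].to_numpy()))
            for comp, grp in scores.groupby("comparison", sort=False)
        }
    ).T
    summary.index.name = "comparison"
    return scores, summary
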