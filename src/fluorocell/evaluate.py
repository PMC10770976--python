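"""Detection scoring: IoU matching, F1 per threshold, and F1avg.

Predictions and ground truths are matched one-to-one at each IoU threshold
tau by maximum bipartite matching on the tau-thresholded IoU graph (which
never understates the number of true positives).  F1 is computed at each
tau in T, default T = (0.5, 0.6, 0.7, 0.8, 0.9), and F1avg is their mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

DEFAULT_TAUS = (0.5, 0.6, 0.7, 0.8, 0.9)


def mask_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """|A n B| / |A u B|; raises if both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share dimensions")
    inter = int(np.logical_and(a, b).sum())
    union = int(a.sum()) + int(b.sum()) - inter
    if union == 0:
        raise ValueError("IoU of two empty masks is undefined")
    return inter / union


def _iou_matrix(pred_masks: list[np.ndarray], gt_masks: list[np.ndarray]) -> np.ndarray:
    iou = np.zeros((len(pred_masks), len(gt_masks)))
    for i, p in enumerate(pred_masks):
        pa = int(p.sum())
        for j, g in enumerate(gt_masks):
            inter = int(np.logical_and(p, g).sum())
            if inter:
                iou[i, j] = inter / (pa + int(g.sum()) - inter)
    return iou


def match_at_tau(
    pred_masks: list[np.ndarray],
    gt_masks: list[np.ndarray],
    tau: float,
    iou: np.ndarray | None = None,
) -> tuple[int, int, int]:
    """Maximum-cardinality one-to-one matching among pairs with IoU >= tau.

    Returns (TP, FP, FN).
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    n_pred, n_gt = len(pred_masks), len(gt_masks)
    if n_pred == 0 or n_gt == 0:
        return 0, n_pred, n_gt
    if iou is None:
        iou = _iou_matrix(pred_masks, gt_masks)
    feasible = (iou >= tau).astype(float)
    rows, cols = linear_sum_assignment(feasible, maximize=True)
    tp = int(feasible[rows, cols].sum())
    return tp, n_pred - tp, n_gt - tp


@dataclass
class EvalReport:
    per_tau: pd.DataFrame  # tau, TP, FP, FN, precision, recall, f1
    f1avg: float
    taus: tuple[float, ...]

    def to_json_dict(self) -> dict:
        return {
            "taus": list(self.taus),
            "per_tau": self.per_tau.to_dict(orient="records"),
            "f1avg": self.f1avg,
        }


def _f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if tp else 0.0
    return precision, recall, f1


def f1avg(
    pred_masks: list[np.ndarray],
    gt_masks: list[np.ndarray],
    taus: tuple[float, ...] = DEFAULT_TAUS,
) -> EvalReport:
    """F1 at each tau plus their mean.

    Both sets empty is perfect vacuous agreement: F1 is defined as 1 there.
    """
    if not taus:
        raise ValueError("threshold set T must be nonempty")
    if any(not 0.0 < t < 1.0 for t in taus):
        raise ValueError("all taus must lie in (0, 1)")
    iou = _iou_matrix(pred_masks, gt_masks) if pred_masks and gt_masks else None
    rows = []
    for tau in taus:
        tp, fp, fn = match_at_tau(pred_masks, gt_masks, tau, iou=iou)
        if tp == fp == fn == 0:
            p = r = f1 = 1.0  # vacuous agreement
        else:
            p, r, f1 = _f1(tp, fp, fn)
        rows.append({"tau": tau, "TP": tp, "FP": fp, "FN": fn,
                     "precision": p, "recall": r, "f1": f1})
    df = pd.DataFrame(rows)
    return EvalReport(per_tau=df, f1avg=float(df["f1"].mean()), taus=tuple(taus))


def f1avg_dataset(
    per_image_pairs: list[tuple[list[np.ndarray], list[np.ndarray]]],
    taus: tuple[float, ...] = DEFAULT_TAUS,
    mode: str = "macro",
) -> float:
    """Aggregate F1avg over an evaluation set.

    ``macro`` (default) averages per-image F1avg scores; ``micro`` pools
    TP/FP/FN counts across images before computing each F1_tau.
    """
    if mode == "macro":
        scores = [f1avg(p, g, taus).f1avg for p, g in per_image_pairs]
        return float(np.mean(scores)) if scores else 1.0
    if mode != "micro":
        raise ValueError("mode must be 'macro' or 'micro'")
    f1s = []
    for tau in taus:
        tp = fp = fn = 0
        for preds, gts in per_image_pairs:
            a, b, c = match_at_tau(preds, gts, tau)
            tp, fp, fn = tp + a, fp + b, fn + c
        if tp == fp == fn == 0:
            f1s.append(1.0)
        else:
            f1s.append(_f1(tp, fp, fn)[2])
    return float(np.mean(f1s))
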