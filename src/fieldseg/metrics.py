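"""Instance-segmentation evaluation: IoU, greedy matching, precision/recall
and mAP@0.5 for the box and mask tracks independently.

Conventions (documented, YOLO-family): predictions are processed in
descending score order (ties broken by input order); each prediction claims
the highest-IoU unclaimed ground truth with IoU >= the threshold; AP uses
101-point interpolation of the precision-recall curve; the single P/R
numbers are computed at a fixed confidence threshold (default 0.25).
Coordinates are 0-based, half-open ``(x1, y1, x2, y2)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "InstancePrediction",
    "GroundTruthInstance",
    "MatchResult",
    "PRCurve",
    "box_iou",
    "mask_iou",
    "match_instances",
    "precision_recall",
    "average_precision",
    "map_at_05",
    "evaluate_dataset",
]


@dataclass
class InstancePrediction:
    box: tuple  # (x1, y1, x2, y2), pixels, half-open
    score: float
    class_id: int = 0
    mask: np.ndarray | None = None  # bool (H, W)

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x2 > x1 and y2 > y1):
            raise ValueError(f"degenerate box {self.box}")


@dataclass
class GroundTruthInstance:
    box: tuple
    class_id: int = 0
    mask: np.ndarray | None = None


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    matches: list = field(default_factory=list)  # (pred_idx, gt_idx, iou)
    pred_flags: np.ndarray | None = None  # per input pred: matched?
    pred_scores: np.ndarray | None = None


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    ap: float


def box_iou(a, b) -> float:
    """IoU of two half-open pixel boxes; 0 when disjoint or union empty."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return float(inter / union) if union > 0 else 0.0


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Pixel IoU of two binary masks of equal shape."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def _pair_iou(p, g, kind: str) -> float:
    if kind == "box":
        return box_iou(p.box, g.box)
    if kind == "mask":
        if p.mask is None or g.mask is None:
            raise ValueError("mask matching requested but masks missing")
        return mask_iou(p.mask, g.mask)
    raise ValueError(f"unknown matching kind {kind!r}")


def match_instances(preds, gts, iou_thr: float = 0.5, kind: str = "box") -> MatchResult:
    """Greedy one-to-one matching in descending score order.

    Returns TP/FP/FN counts satisfying TP+FN = len(gts), TP+FP = len(preds),
    plus per-prediction hit flags in the *input* order (for AP accumulation).
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    claimed = [False] * len(gts)
    flags = np.zeros(len(preds), bool)
    matches = []
    for pi in order:
        best_iou, best_gi = iou_thr, -1
        for gi, g in enumerate(gts):
            if claimed[gi] or g.class_id != preds[pi].class_id:
                continue
            iou = _pair_iou(preds[pi], g, kind)
            if iou >= best_iou and (best_gi < 0 or iou > best_iou):
                best_iou, best_gi = iou, gi
        if best_gi >= 0:
            claimed[best_gi] = True
            flags[pi] = True
            matches.append((pi, best_gi, best_iou))
    tp = int(flags.sum())
    return MatchResult(
        tp=tp,
        fp=len(preds) - tp,
        fn=len(gts) - tp,
        matches=matches,
        pred_flags=flags,
        pred_scores=np.array([p.score for p in preds], float),
    )


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); 0 on empty denominators."""
    p = m.tp / (m.tp + m.fp) if m.tp + m.fp else 0.0
    r = m.tp / (m.tp + m.fn) if m.tp + m.fn else 0.0
    return p, r


def average_precision(scores: np.ndarray, hits: np.ndarray, n_gt: int) -> PRCurve:
    """AP by 101-point interpolation from scored match flags.

    ``scores``/``hits`` are per-prediction over the whole dataset; ``n_gt``
    the total ground-truth count (must be positive).
    """
    if n_gt <= 0:
        raise ValueError("average precision undefined with zero ground truths")
    scores = np.asarray(scores, float)
    hits = np.asarray(hits, bool)
    if len(scores) == 0:
        return PRCurve(recall=np.zeros(0), precision=np.zeros(0), ap=0.0)
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(hits[order])
    fp = np.cumsum(~hits[order])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope, sampled at 101 recall points
    r_pts = np.linspace(0, 1, 101)
    prec_env = precision.copy()
    for i in range(len(prec_env) - 2, -1, -1):
        prec_env[i] = max(prec_env[i], prec_env[i + 1])
    idx = np.searchsorted(recall, r_pts, side="left")
    sampled = np.where(idx < len(prec_env), prec_env[np.minimum(idx, len(prec_env) - 1)], 0.0)
    return PRCurve(recall=recall, precision=precision, ap=float(sampled.mean()))


def map_at_05(per_class_aps) -> float:
    """Mean over per-class APs."""
    aps = list(per_class_aps)
    if not aps:
        raise ValueError("no classes to average")
    return float(np.mean(aps))


def evaluate_dataset(
    preds_per_image,
    gts_per_image,
    kind: str = "box",
    iou_thr: float = 0.5,
    conf_thr: float = 0.25,
) -> dict:
    """P/R (at ``conf_thr``) and mAP@``iou_thr`` over a list of images.

    ``preds_per_image``/``gts_per_image`` are parallel lists of instance
    lists.  Returns per-class AP and the aggregate precision/recall/mAP.
    """
    if len(preds_per_image) != len(gts_per_image):
        raise ValueError("prediction/ground-truth image counts differ")
    classes = sorted(
        {g.class_id for gl in gts_per_image for g in gl}
    ) or [0]
    all_scores: dict[int, list] = {c: [] for c in classes}
    all_hits: dict[int, list] = {c: [] for c in classes}
    n_gt = {c: 0 for c in classes}
    tp = fp = fn = 0
    for preds, gts in zip(preds_per_image, gts_per_image):
        for c in classes:
            pc = [p for p in preds if p.class_id == c]
            gc = [g for g in gts if g.class_id == c]
            m = match_instances(pc, gc, iou_thr, kind)
            all_scores[c].extend(m.pred_scores)
            all_hits[c].extend(m.pred_flags)
            n_gt[c] += len(gc)
            # fixed-confidence P/R bookkeeping
            mc = match_instances([p for p in pc if p.score >= conf_thr], gc, iou_thr, kind)
            tp += mc.tp
            fp += mc.fp
            fn += mc.fn
    per_class_ap = {}
    for c in classes:
        if n_gt[c] == 0:
            continue
        per_class_ap[c] = average_precision(
            np.array(all_scores[c]), np.array(all_hits[c]), n_gt[c]
        ).ap
    result = {
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "per_class_ap": per_class_ap,
        "map": map_at_05(per_class_ap.values()) if per_class_ap else 0.0,
    }
    return result


def write_metrics_report(path, box_metrics: dict, mask_metrics: dict) -> None:
    """Write the Box/Mask metric columns as a JSON report."""
    report = {
        "P-Box": box_metrics["precision"],
        "R-Box": box_metrics["recall"],
        "mAP@0.5-Box": box_metrics["map"],
        "P-Mask": mask_metrics["precision"],
        "R-Mask": mask_metrics["recall"],
        "mAP@0.5-Mask": mask_metrics["map"],
    }
    Path(path).write_text(json.dumps(report, indent=2))
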