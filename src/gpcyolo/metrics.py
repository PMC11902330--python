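"""Detection metrics: matching, precision/recall, AP and mAP.

Definitions: ``P = TP/(TP+FP)``, ``R = TP/(TP+FN)``; AP is the area under
the precision-recall curve computed with all-point interpolation on the
monotone precision envelope; mAP is the unweighted mean of per-class AP.
``mAP50`` evaluates at IoU 0.5, ``mAP50:95`` averages the ten thresholds
0.50, 0.55, ..., 0.95.

Matching is greedy by descending confidence, one-to-one, within class: a
detection is a true positive if it overlaps a still-unmatched ground truth
of its class at IoU >= threshold; remaining detections are false positives
and remaining ground truths false negatives.  Confidence ties are broken
by (image id, detection index) so results are order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .boxes import Box, iou

__all__ = [
    "DetectionCounts", "MatchConfig", "MetricsReport",
    "match_detections", "precision_recall", "average_precision",
    "mean_average_precision", "evaluate_detections", "MAP_50_95_THRESHOLDS",
]

MAP_50_95_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass
class DetectionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class MatchConfig:
    iou_threshold: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.iou_threshold <= 1.0):
            raise ValueError(f"iou_threshold must be in (0, 1], got {self.iou_threshold}")


@dataclass
class MetricsReport:
    """Per-class and aggregate detection quality."""

    per_class: Dict[int, Dict[str, float]]
    mAP50: float
    mAP50_95: float
    n_classes: int
    counts: Dict[int, DetectionCounts] = field(default_factory=dict)


def match_detections(preds: Sequence[Box], gts: Sequence[Box],
                     cfg: MatchConfig = MatchConfig()
                     ) -> Tuple[DetectionCounts, List[bool]]:
    """Greedy one-to-one matching of same-class detections to ground truth.

    Returns aggregate counts plus a TP/FP flag per detection in descending
    confidence order (the ranking AP consumes).
    """
    order = sorted(range(len(preds)),
                   key=lambda i: (-(preds[i].confidence or 0.0), i))
    matched = [False] * len(gts)
    flags: List[bool] = []
    tp = 0
    for i in order:
        p = preds[i]
        best, best_iou = -1, cfg.iou_threshold
        for j, g in enumerate(gts):
            if matched[j] or g.class_id != p.class_id:
                continue
            ov = iou(p, g)
            if ov >= best_iou:
                best, best_iou = j, ov
        if best >= 0:
            matched[best] = True
            tp += 1
            flags.append(True)
        else:
            flags.append(False)
    fn = matched.count(False)
    return DetectionCounts(tp=tp, fp=len(preds) - tp, fn=fn), flags


def precision_recall(c: DetectionCounts) -> Tuple[float, float]:
    """Exact ratios; 0 when the denominator is empty."""
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return p, r


def average_precision(flags: Sequence[bool], n_gt: int) -> float:
    """Area under the monotone P-R envelope for a ranked TP/FP sequence.

    ``flags`` must already be sorted by descending confidence.  With no
    ground truth the value is undefined and a ``ValueError`` is raised
    (callers exclude such classes from the mean).
    """
    if n_gt <= 0:
        raise ValueError("average precision undefined without ground truth")
    if not flags:
        return 0.0
    tp = np.cumsum(np.asarray(flags, dtype=float))
    fp = np.cumsum(~np.asarray(flags, dtype=bool))
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # prepend/append sentinels, enforce the monotone envelope
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    idx = np.nonzero(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def mean_average_precision(per_class_ap: Sequence[float]) -> float:
    """Unweighted mean over classes (classes without ground truth excluded
    upstream)."""
    if len(per_class_ap) == 0:
        raise ValueError("no classes with ground truth to average")
    return float(np.mean(per_class_ap))


def _per_image_class(boxes: Sequence[Sequence[Box]], cid: int
                     ) -> List[List[Box]]:
    return [[b for b in img if b.class_id == cid] for img in boxes]


def evaluate_detections(preds: Sequence[Sequence[Box]],
                        gts: Sequence[Sequence[Box]],
                        num_classes: int,
                        iou_threshold: float = 0.5) -> MetricsReport:
    """Full pipeline over a set of images.

    ``preds[i]``/``gts[i]`` are the detections and ground truths of image
    ``i``.  Classes with zero ground truth are excluded from the class
    means with a warning.
    """
    if len(preds) != len(gts):
        raise ValueError("preds and gts must cover the same images")
    per_class: Dict[int, Dict[str, float]] = {}
    counts: Dict[int, DetectionCounts] = {}
    ap50_list, ap5095_list = [], []
    for cid in range(num_classes):
        cp, cg = _per_image_class(preds, cid), _per_image_class(gts, cid)
        n_gt = sum(len(g) for g in cg)
        if n_gt == 0:
            warnings.warn(f"class {cid} has no ground truth; excluded from mAP")
            continue
        # pooled ranking across images with deterministic tie-breaks
        pool = [(-(b.confidence or 0.0), i, k, b)
                for i, img in enumerate(cp) for k, b in enumerate(img)]
        pool.sort(key=lambda t: t[:3])
        def ranked_flags(thr: float) -> Tuple[List[bool], int]:
            matched = [[False] * len(g) for g in cg]
            flags: List[bool] = []
            tp_tot = 0
            for _, i, _, p in pool:
                best, best_iou = -1, thr
                for j, g in enumerate(cg[i]):
                    if matched[i][j]:
                        continue
                    ov = iou(p, g)
                    if ov >= best_iou:
                        best, best_iou = j, ov
                if best >= 0:
                    matched[i][best] = True
                    flags.append(True)
                    tp_tot += 1
                else:
                    flags.append(False)
            return flags, tp_tot

        aps = {}
        for thr in MAP_50_95_THRESHOLDS:
            aps[thr] = average_precision(ranked_flags(float(thr))[0], n_gt)
        tp_tot = ranked_flags(iou_threshold)[1]
        counts[cid] = DetectionCounts(tp=tp_tot, fp=len(pool) - tp_tot,
                                      fn=n_gt - tp_tot)
        ap50 = aps[0.5]
        ap5095 = float(np.mean([aps[t] for t in MAP_50_95_THRESHOLDS]))
        p, r = precision_recall(counts[cid])
        per_class[cid] = {"P": p, "R": r, "AP50": ap50, "AP50_95": ap5095}
        ap50_list.append(ap50)
        ap5095_list.append(ap5095)
    return MetricsReport(
        per_class=per_class,
        mAP50=mean_average_precision(ap50_list),
        mAP50_95=mean_average_precision(ap5095_list),
        n_classes=len(ap50_list),
        counts=counts,
    )
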