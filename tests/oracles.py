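"""Independent brute-force oracles used by several test modules.

These re-derive every quantity directly from the printed definitions on
raw corner coordinates / flag lists, sharing no geometry code with the
package, so agreement is a genuine two-route check.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

EPS = 1e-7  # same documented denominator guard as the implementation


def oracle_iou(a: Tuple[float, float, float, float],
               b: Tuple[float, float, float, float]) -> float:
    """IoU from center-form tuples (cx, cy, w, h) by direct area arithmetic."""
    ax1, ay1, ax2, ay2 = a[0] - a[2] / 2, a[1] - a[3] / 2, a[0] + a[2] / 2, a[1] + a[3] / 2
    bx1, by1, bx2, by2 = b[0] - b[2] / 2, b[1] - b[3] / 2, b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = a[2] * a[3] + b[2] * b[3] - inter
    return inter / union if union > 0 else 0.0


def oracle_ciou(p, g) -> float:
    """CIoU loss evaluated term by term from its definition."""
    ov = oracle_iou(p, g)
    rho2 = (p[0] - g[0]) ** 2 + (p[1] - g[1]) ** 2
    wc = max(p[0] + p[2] / 2, g[0] + g[2] / 2) - min(p[0] - p[2] / 2, g[0] - g[2] / 2)
    hc = max(p[1] + p[3] / 2, g[1] + g[3] / 2) - min(p[1] - p[3] / 2, g[1] - g[3] / 2)
    c2 = wc * wc + hc * hc
    v = 4.0 / math.pi ** 2 * (math.atan(g[2] / (g[3] + EPS))
                              - math.atan(p[2] / (p[3] + EPS))) ** 2
    denom = (1.0 - ov) + v
    alpha = 0.0 if denom <= EPS else v / denom
    return (1.0 - ov) + rho2 / (c2 + EPS) + alpha * v


def oracle_eiou(p, g) -> float:
    """EIoU loss evaluated term by term from its definition."""
    ov = oracle_iou(p, g)
    rho2 = (p[0] - g[0]) ** 2 + (p[1] - g[1]) ** 2
    wc = max(p[0] + p[2] / 2, g[0] + g[2] / 2) - min(p[0] - p[2] / 2, g[0] - g[2] / 2)
    hc = max(p[1] + p[3] / 2, g[1] + g[3] / 2) - min(p[1] - p[3] / 2, g[1] - g[3] / 2)
    return ((1.0 - ov) + rho2 / (wc * wc + hc * hc + EPS)
            + (p[2] - g[2]) ** 2 / (wc * wc + EPS)
            + (p[3] - g[3]) ** 2 / (hc * hc + EPS))


# ---------------------------------------------------------------------
# metrics oracle: direct evaluation of P, R, AP, mAP definitions
# ---------------------------------------------------------------------

def oracle_metrics(preds: Sequence[Sequence], gts: Sequence[Sequence],
                   num_classes: int, thresholds: Sequence[float]):
    """preds/gts are per-image lists of (class, cx, cy, w, h[, conf]) tuples.

    Returns {class: {thr: ap}} plus mAP values, computed with its own
    greedy matcher and a rectangle-sum under the precision envelope.
    """
    out = {}
    for cid in range(num_classes):
        n_gt = sum(1 for img in gts for g in img if g[0] == cid)
        if n_gt == 0:
            continue
        ranked = sorted(((p[5], i, k, p) for i, img in enumerate(preds)
                         for k, p in enumerate(img) if p[0] == cid),
                        key=lambda t: (-t[0], t[1], t[2]))
        out[cid] = {}
        for thr in thresholds:
            used = set()
            flags: List[bool] = []
            for _, i, _, p in ranked:
                cands = [(j, oracle_iou(p[1:5], g[1:5]))
                         for j, g in enumerate(gts[i])
                         if g[0] == cid and (i, j) not in used]
                cands = [(j, o) for j, o in cands if o >= thr]
                if cands:
                    j = max(cands, key=lambda t: t[1])[0]
                    used.add((i, j))
                    flags.append(True)
                else:
                    flags.append(False)
            # AP: walk recall levels, take max precision at recall >= r
            pr = []
            tp = fp = 0
            for f in flags:
                tp, fp = tp + f, fp + (not f)
                pr.append((tp / n_gt, tp / (tp + fp)))
            ap = 0.0
            prev_r = 0.0
            for r in sorted(set(p[0] for p in pr)):
                pmax = max((pp for rr, pp in pr if rr >= r), default=0.0)
                ap += (r - prev_r) * pmax
                prev_r = r
            out[cid][thr] = ap
    return out
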