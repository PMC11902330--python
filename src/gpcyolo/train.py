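"""Loss assembly and the training loop.

The composite detection loss follows the stock anchor-free recipe — binary
cross-entropy classification with task-aligned soft targets, a
distribution-focal (DFL) term on the discretized box edges — with the box
regression term swapped from CIoU to EIoU, which penalizes width/height
differences directly.  Loss weights default to box 7.5 / cls 0.5 /
dfl 1.5.

Assignment is task-aligned: anchors whose center lies inside a ground-truth
box are candidates; the top-10 by ``score^0.5 * IoU^6`` are taken per box,
each anchor keeping only its highest-overlap box; classification targets
are the one-hot class scaled by the normalized alignment metric.

The optimizer is SGD with momentum 0.937, weight decay 0.0005 (applied to
convolution weights only) and a linear decay of the learning rate from
``lr0 = 0.01`` to ``lr0/100``; defaults mirror the published training
protocol (batch 16, 640 px, 300 epochs).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .boxes import EPS
from .network import Model, letterbox, make_anchors, save_weights
from .nn.layers import Detect
from .nn.tensor import Tensor, concat, no_grad

__all__ = [
    "TrainConfig", "AssignmentResult", "SGD", "detection_loss",
    "eiou_loss_xyxy", "ciou_loss_xyxy", "task_aligned_assign", "train",
    "prepare_samples",
]


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults = the published protocol)."""

    batch_size: int = 16
    momentum: float = 0.937
    weight_decay: float = 0.0005
    lr0: float = 0.01
    lrf: float = 0.01           # final lr = lr0 * lrf (linear decay)
    epochs: int = 300
    input_size: int = 640
    seed: int = 0
    loss_weights: Tuple[float, float, float] = (7.5, 0.5, 1.5)  # box, cls, dfl
    iou_type: str = "eiou"      # "eiou" (default) or "ciou"
    tal_topk: int = 10
    tal_alpha: float = 0.5
    tal_beta: float = 6.0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if min(self.momentum, self.weight_decay, self.lr0) < 0:
            raise ValueError("optimizer hyperparameters must be non-negative")
        if self.iou_type not in ("eiou", "ciou"):
            raise ValueError(f"iou_type must be 'eiou' or 'ciou', got {self.iou_type}")


@dataclass
class AssignmentResult:
    """Anchor-to-ground-truth assignment for one batch."""

    fg_mask: np.ndarray        # (N, A) bool
    target_boxes: np.ndarray   # (N, A, 4) xyxy, input pixels
    target_scores: np.ndarray  # (N, A, nc) soft classification targets


# ---------------------------------------------------------------------
# vectorized IoU losses on tensors (gradient-carrying)
# ---------------------------------------------------------------------

def _xyxy_parts(t: Tensor):
    return t[:, 0], t[:, 1], t[:, 2], t[:, 3]


def _pairwise_terms(pred: Tensor, target: np.ndarray):
    tgt = Tensor(np.asarray(target, dtype=np.float32))
    px1, py1, px2, py2 = _xyxy_parts(pred)
    tx1, ty1, tx2, ty2 = _xyxy_parts(tgt)
    iw = px2.minimum(tx2) - px1.maximum(tx1)
    ih = py2.minimum(ty2) - py1.maximum(ty1)
    inter = iw.maximum(0.0) * ih.maximum(0.0)
    ap = (px2 - px1) * (py2 - py1)
    ag = (tx2 - tx1) * (ty2 - ty1)
    union = ap + ag - inter
    ov = inter / (union + EPS)
    wc = px2.maximum(tx2) - px1.minimum(tx1)
    hc = py2.maximum(ty2) - py1.minimum(ty1)
    rho2 = ((px1 + px2 - tx1 - tx2) * 0.5) ** 2 + ((py1 + py2 - ty1 - ty2) * 0.5) ** 2
    return ov, wc, hc, rho2, (px2 - px1, py2 - py1, tx2 - tx1, ty2 - ty1)


def eiou_loss_xyxy(pred: Tensor, target: np.ndarray) -> Tensor:
    """Per-pair EIoU loss on corner-form boxes; shape (M,)."""
    ov, wc, hc, rho2, (pw, ph, tw, th) = _pairwise_terms(pred, target)
    return ((1.0 - ov)
            + rho2 / (wc * wc + hc * hc + EPS)
            + (pw - tw) ** 2 / (wc * wc + EPS)
            + (ph - th) ** 2 / (hc * hc + EPS))


def ciou_loss_xyxy(pred: Tensor, target: np.ndarray) -> Tensor:
    """Per-pair CIoU loss (aspect-ratio penalty, trade-off alpha detached)."""
    ov, wc, hc, rho2, (pw, ph, tw, th) = _pairwise_terms(pred, target)
    t_ar = np.arctan(tw.data / (th.data + EPS))       # targets carry no grad
    v = (4.0 / math.pi ** 2) * (Tensor(t_ar) - (pw / (ph + EPS)).arctan()) ** 2
    alpha = Tensor(v.data / (1.0 - ov.data + v.data + EPS))  # detached, as stock
    return (1.0 - ov) + rho2 / (wc * wc + hc * hc + EPS) + alpha * v


# ---------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------

def task_aligned_assign(scores_sig: np.ndarray, pred_boxes: np.ndarray,
                        anchor_pts: np.ndarray,
                        gt_boxes: List[np.ndarray], gt_cls: List[np.ndarray],
                        nc: int, topk: int = 10, alpha: float = 0.5,
                        beta: float = 6.0) -> AssignmentResult:
    """Task-aligned label assignment (pure NumPy, no gradients).

    ``scores_sig``: (N, A, nc) sigmoid class scores; ``pred_boxes``:
    (N, A, 4) xyxy in input pixels; ``anchor_pts``: (A, 2) anchor centers
    in input pixels; ``gt_boxes[i]``: (Mi, 4) xyxy pixels.
    """
    n, a, _ = scores_sig.shape
    fg = np.zeros((n, a), dtype=bool)
    tboxes = np.zeros((n, a, 4), dtype=np.float32)
    tscores = np.zeros((n, a, nc), dtype=np.float32)
    for i in range(n):
        gb, gc = gt_boxes[i], gt_cls[i]
        m = len(gb)
        if m == 0:
            continue
        inside = ((anchor_pts[None, :, 0] > gb[:, None, 0])
                  & (anchor_pts[None, :, 0] < gb[:, None, 2])
                  & (anchor_pts[None, :, 1] > gb[:, None, 1])
                  & (anchor_pts[None, :, 1] < gb[:, None, 3]))      # (M, A)
        ov = _iou_matrix(pred_boxes[i], gb)                          # (A, M)
        ov = ov.T                                                    # (M, A)
        cls_score = scores_sig[i][:, gc].T                           # (M, A)
        align = (cls_score ** alpha) * (ov ** beta) * inside
        # top-k candidates per ground truth
        mask = np.zeros_like(align, dtype=bool)
        k = min(topk, a)
        top = np.argpartition(-align, k - 1, axis=1)[:, :k]
        rows = np.arange(m)[:, None]
        mask[rows, top] = align[rows, top] > 0
        # resolve anchors claimed by several boxes: keep highest overlap
        claimed = mask.sum(axis=0) > 1
        if claimed.any():
            best_gt = ov.argmax(axis=0)
            forced = np.zeros_like(mask)
            forced[best_gt[claimed], np.nonzero(claimed)[0]] = True
            mask[:, claimed] = forced[:, claimed]
        fg[i] = mask.any(axis=0)
        gt_idx = mask.argmax(axis=0)
        tboxes[i] = gb[gt_idx]
        # normalized alignment -> soft class targets
        ametric = align * mask
        denom = ametric.max(axis=1, keepdims=True) + EPS
        omax = (ov * mask).max(axis=1, keepdims=True)
        norm = ametric / denom * omax                                # (M, A)
        val = norm[gt_idx, np.arange(a)]
        onehot = np.zeros((a, nc), dtype=np.float32)
        onehot[np.arange(a), gc[gt_idx]] = val
        tscores[i] = onehot * fg[i][:, None]
    return AssignmentResult(fg, tboxes, tscores)


def _iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU between each row of ``a`` (A,4) and ``b`` (M,4), xyxy."""
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None] - inter
    return np.where(union > 0, inter / union, 0.0)


# ---------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------

def detection_loss(outs: List[Tensor], targets: List[np.ndarray],
                   cfg: TrainConfig, strides: Sequence[int], nc: int
                   ) -> Tuple[Tensor, float, float, float]:
    """Composite loss for one batch.

    ``outs``: per-scale raw head maps (N, 4*16+nc, H, W); ``targets[i]``:
    (Mi, 5) rows ``class, cx, cy, w, h`` normalized to the model input.
    Returns ``(total, box_term, cls_term, dfl_term)`` where the box term is
    the mean EIoU (or CIoU) over assigned anchor/box pairs.
    """
    reg = Detect.REG_MAX
    n = outs[0].data.shape[0]
    size = outs[0].data.shape[2] * strides[0]
    shapes = [o.data.shape[2:] for o in outs]
    pts, sts = make_anchors(shapes, strides)          # grid units / strides
    a = pts.shape[0]
    flat = concat([o.reshape(o.data.shape[0], o.data.shape[1], -1) for o in outs],
                  axis=2).transpose(0, 2, 1)          # (N, A, 4reg+nc)
    pd_dist = flat[:, :, : 4 * reg]
    pd_cls = flat[:, :, 4 * reg:]
    # distribution expectation -> ltrb distances (grid units)
    dist = pd_dist.reshape(n, a, 4, reg).softmax(axis=-1)
    proj = np.arange(reg, dtype=np.float32).reshape(1, 1, 1, reg)
    ltrb = (dist * Tensor(proj)).sum(axis=-1)         # (N, A, 4)
    xy1 = Tensor(pts[None]) - ltrb[:, :, :2]
    xy2 = Tensor(pts[None]) + ltrb[:, :, 2:]
    pboxes_grid = concat([xy1, xy2], axis=-1)         # (N, A, 4) grid units
    pboxes_px = pboxes_grid.data * sts[None]          # detached, pixels
    anchor_px = pts * sts

    gt_boxes, gt_cls = [], []
    for t in targets:
        t = np.asarray(t, dtype=np.float32).reshape(-1, 5)
        cxy, wh = t[:, 1:3] * size, t[:, 3:5] * size
        gt_boxes.append(np.concatenate([cxy - wh / 2, cxy + wh / 2], axis=1))
        gt_cls.append(t[:, 0].astype(int))
    with no_grad():
        scores_sig = 1.0 / (1.0 + np.exp(-pd_cls.data))
        asg = task_aligned_assign(scores_sig, pboxes_px, anchor_px,
                                  gt_boxes, gt_cls, nc,
                                  cfg.tal_topk, cfg.tal_alpha, cfg.tal_beta)
    tsum = max(float(asg.target_scores.sum()), 1.0)
    cls_term = pd_cls.bce_with_logits(asg.target_scores).sum() * (1.0 / tsum)

    bi, ai = np.nonzero(asg.fg_mask)
    if len(bi) == 0:
        zero = Tensor(np.zeros(()))
        total = cfg.loss_weights[1] * cls_term
        return total, 0.0, cls_term.item(), 0.0
    st_fg = sts[ai, 0]
    tgt_grid = asg.target_boxes[bi, ai] / st_fg[:, None]
    pred_fg = pboxes_grid[bi, ai]                     # (M, 4) tensor
    pair_loss = (eiou_loss_xyxy if cfg.iou_type == "eiou" else ciou_loss_xyxy)(
        pred_fg, tgt_grid)
    box_term = pair_loss.mean()

    # distribution-focal targets: distances to the two adjacent bins
    t_ltrb = np.concatenate([pts[ai] - tgt_grid[:, :2],
                             tgt_grid[:, 2:] - pts[ai]], axis=1)
    t_ltrb = np.clip(t_ltrb, 0, reg - 1 - 0.01)
    tl = np.floor(t_ltrb)
    wr = t_ltrb - tl
    wl = 1.0 - wr
    m = len(bi)
    tdist = np.zeros((m, 4, reg), dtype=np.float32)
    rows = np.repeat(np.arange(m), 4)
    cols = np.tile(np.arange(4), m)
    tdist[rows, cols, tl.astype(int).ravel()] = wl.ravel()
    np.add.at(tdist, (rows, cols, np.minimum(tl.astype(int) + 1, reg - 1).ravel()),
              wr.ravel())
    ls = pd_dist[bi, ai].reshape(m, 4, reg).log_softmax(axis=-1)
    dfl_term = -(ls * Tensor(tdist)).sum(axis=-1).mean()

    wb, wc_, wd = cfg.loss_weights
    total = wb * box_term + wc_ * cls_term + wd * dfl_term
    for name, t in (("box", box_term), ("cls", cls_term), ("dfl", dfl_term)):
        if not np.isfinite(t.data).all():
            raise RuntimeError(f"non-finite {name} loss term")
    return total, box_term.item(), cls_term.item(), dfl_term.item()


# ---------------------------------------------------------------------
# optimizer + loop
# ---------------------------------------------------------------------

class SGD:
    """SGD with momentum; weight decay applied to >=2-D weights only
    (convolution kernels), never to norm scales or biases."""

    def __init__(self, params, lr: float, momentum: float = 0.937,
                 weight_decay: float = 0.0005):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim >= 2:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


def evaluate_model(model: Model, samples: Sequence[Tuple[np.ndarray, Sequence]],
                   conf_thresh: float = 0.25, iou_thresh: float = 0.45,
                   match_iou: float = 0.5):
    """Run inference over ``(image, gt_boxes_px)`` samples and score them.

    ``gt_boxes_px`` are ground-truth :class:`~gpcyolo.boxes.Box` in pixel
    units of the image.  Returns a :class:`~gpcyolo.metrics.MetricsReport`.
    """
    from .metrics import evaluate_detections
    from .network import predict

    preds = [predict(model, img, conf_thresh, iou_thresh) for img, _ in samples]
    gts = [list(g) for _, g in samples]
    return evaluate_detections(preds, gts, model.cfg.num_classes, match_iou)


def recalibrate_bn(model: Model, batches: Sequence[np.ndarray]) -> None:
    """Recompute batch-norm running statistics with the current weights
    ("precise BN"): resets the running averages and replays the given
    batches in training mode without gradients.  Necessary whenever the
    number of optimizer steps was too small for the exponential averages
    to track the final weights."""
    from .nn.layers import BatchNorm2d

    for m in model._modules:
        for sub in m.modules():
            if isinstance(sub, BatchNorm2d):
                sub.reset_running_stats()
    model.train()
    with no_grad():
        for x in batches:
            model(x)
    model.eval()


def prepare_samples(samples: Sequence[Tuple[np.ndarray, np.ndarray]],
                    input_size: int) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Letterbox images to the model input and remap normalized labels."""
    out = []
    for img, labels in samples:
        h, w = img.shape[:2]
        padded, r, (dx, dy) = letterbox(img, input_size)
        lab = np.asarray(labels, dtype=np.float32).reshape(-1, 5).copy()
        if len(lab):
            lab[:, 1] = (lab[:, 1] * w * r + dx) / input_size
            lab[:, 2] = (lab[:, 2] * h * r + dy) / input_size
            lab[:, 3] = lab[:, 3] * w * r / input_size
            lab[:, 4] = lab[:, 4] * h * r / input_size
        x = padded.astype(np.float32).transpose(2, 0, 1) / 255.0
        out.append((x, lab))
    return out


def train(model: Model, dataset: Sequence[Tuple[np.ndarray, np.ndarray]],
          cfg: TrainConfig, out_dir: Optional[Path] = None,
          log_every: int = 1) -> List[Dict]:
    """Train ``model`` on ``(image HxWx3 uint8, labels (M,5)) `` samples.

    Deterministic given ``cfg.seed``.  Returns per-epoch records
    ``{epoch, loss, box, cls, dfl, lr}``; if ``out_dir`` is given, writes a
    JSONL log plus ``last.npz``/``best.npz`` checkpoints (best = lowest
    running loss).  The dataset on disk is never touched.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    prepared = prepare_samples(dataset, cfg.input_size)
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), cfg.lr0, cfg.momentum, cfg.weight_decay)
    nc = model.cfg.num_classes
    records: List[Dict] = []
    best = math.inf
    log_f = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log_f = open(out_dir / "train_log.jsonl", "w")
    try:
        for epoch in range(cfg.epochs):
            model.train()
            frac = epoch / max(cfg.epochs - 1, 1)
            opt.lr = cfg.lr0 * (1.0 - frac * (1.0 - cfg.lrf))
            order = rng.permutation(len(prepared))
            tot = np.zeros(4)
            nb = 0
            for s in range(0, len(order), cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                x = np.stack([prepared[i][0] for i in idx])
                tgt = [prepared[i][1] for i in idx]
                outs = model(x)
                loss, b, c, d = detection_loss(outs, tgt, cfg, model.strides, nc)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"NaN/Inf total loss at epoch {epoch} "
                        f"(box={b:.4g}, cls={c:.4g}, dfl={d:.4g})")
                opt.zero_grad()
                loss.backward()
                opt.step()
                tot += (loss.item(), b, c, d)
                nb += 1
            rec = {"epoch": epoch, "loss": tot[0] / nb, "box": tot[1] / nb,
                   "cls": tot[2] / nb, "dfl": tot[3] / nb, "lr": opt.lr}
            records.append(rec)
            if log_f and epoch % log_every == 0:
                log_f.write(json.dumps(rec) + "\n")
                log_f.flush()
            if out_dir is not None:
                save_weights(model, out_dir / "last.npz")
                if rec["loss"] < best:
                    best = rec["loss"]
                    save_weights(model, out_dir / "best.npz")
        # final-weight batch-norm statistics for inference
        xs = [np.stack([prepared[i][0] for i in idx])
              for idx in np.array_split(np.arange(len(prepared)),
                                        max(len(prepared) // cfg.batch_size, 1))]
        recalibrate_bn(model, xs)
        if out_dir is not None:
            save_weights(model, out_dir / "last.npz")
    finally:
        if log_f:
            log_f.close()
    return records
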