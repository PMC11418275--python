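"""Desk-scale training with the published optimizer settings.

The loss composition is the YOLOv8 convention the architecture inherits:
task-aligned assignment of anchors to ground truth, binary cross-entropy on
class scores against soft IoU-derived targets, complete-IoU regression on
assigned boxes, and distribution focal loss on the two bin neighbours of the
target box-side distances. Optimized with SGD (lr 0.01, momentum 0.937,
weight decay 0.0005, batch size 4 by default).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .blocks import DFL_BINS
from .boxes import iou_matrix
from .infer import decode_and_nms, letterbox
from .metrics import DetectionMetrics, evaluate_detections
from .model import Detector
from .tensor import Tensor, no_grad

__all__ = ["TrainConfig", "SGD", "detection_loss", "train", "evaluate_model"]


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 4
    lr: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    imgsz: int = 640
    box_gain: float = 7.5
    cls_gain: float = 0.5
    dfl_gain: float = 1.5
    warmup_epochs: int = 3
    grad_clip: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("epochs", "batch_size", "lr", "momentum", "weight_decay", "imgsz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class SGD:
    """Stochastic gradient descent with classical momentum and L2 decay."""

    def __init__(self, params, lr, momentum=0.937, weight_decay=0.0005):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self, grad_clip: float | None = None):
        if grad_clip:
            total = 0.0
            for p in self.params:
                if p.grad is not None:
                    total += float((p.grad ** 2).sum())
            norm = np.sqrt(total)
            scale = min(1.0, grad_clip / (norm + 1e-12))
        else:
            scale = 1.0
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad * scale + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# anchors, decoding with gradients
# ---------------------------------------------------------------------------
def _anchor_grid(hw_per_scale, strides):
    centers, stride_vec = [], []
    for (h, w), s in zip(hw_per_scale, strides):
        ys, xs = np.mgrid[0:h, 0:w]
        centers.append(np.stack([(xs.ravel() + 0.5) * s, (ys.ravel() + 0.5) * s], axis=1))
        stride_vec.append(np.full(h * w, s, dtype=np.float64))
    return np.concatenate(centers), np.concatenate(stride_vec)


def _decode_boxes(box_logits: Tensor, centers: np.ndarray, strides: np.ndarray) -> Tensor:
    """(B, A, 4*BINS) logits -> (B, A, 4) xyxy, differentiable."""
    b, a, _ = box_logits.shape
    probs = box_logits.reshape(b, a, 4, DFL_BINS).softmax(axis=3)
    bins = Tensor(np.arange(DFL_BINS, dtype=np.float32).reshape(1, 1, 1, DFL_BINS))
    dist = (probs * bins).sum(axis=3)                      # (b,a,4) in cell units
    dist = dist * Tensor(strides.reshape(1, -1, 1).astype(np.float32))
    cx = Tensor(centers[None, :, 0:1].astype(np.float32))
    cy = Tensor(centers[None, :, 1:2].astype(np.float32))
    x1 = cx - dist[:, :, 0:1]
    y1 = cy - dist[:, :, 1:2]
    x2 = cx + dist[:, :, 2:3]
    y2 = cy + dist[:, :, 3:4]
    return Tensor.concat([x1, y1, x2, y2], axis=2)


def _ciou(pred: Tensor, target: np.ndarray) -> Tensor:
    """Complete IoU between (n,4) predicted boxes and matched targets."""
    t = Tensor(target.astype(np.float32))
    eps = 1e-7
    ix1 = pred[:, 0].maximum(t[:, 0])
    iy1 = pred[:, 1].maximum(t[:, 1])
    ix2 = pred[:, 2].minimum(t[:, 2])
    iy2 = pred[:, 3].minimum(t[:, 3])
    iw = (ix2 - ix1).maximum(0.0)
    ih = (iy2 - iy1).maximum(0.0)
    inter = iw * ih
    pw = (pred[:, 2] - pred[:, 0]).maximum(eps)
    ph = (pred[:, 3] - pred[:, 1]).maximum(eps)
    tw = t[:, 2] - t[:, 0]
    th = t[:, 3] - t[:, 1]
    union = pw * ph + tw * th - inter + eps
    iou = inter / union
    # enclosing box diagonal and centre distance
    ex1 = pred[:, 0].minimum(t[:, 0])
    ey1 = pred[:, 1].minimum(t[:, 1])
    ex2 = pred[:, 2].maximum(t[:, 2])
    ey2 = pred[:, 3].maximum(t[:, 3])
    c2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2 + eps
    rho2 = ((pred[:, 0] + pred[:, 2]) - (t[:, 0] + t[:, 2])) ** 2 * 0.25 + \
           ((pred[:, 1] + pred[:, 3]) - (t[:, 1] + t[:, 3])) ** 2 * 0.25
    v = (4.0 / np.pi ** 2) * ((tw / th.maximum(eps)).atan() - (pw / ph).atan()) ** 2
    alpha = (v / (1.0 - iou + v + eps)).detach()
    return iou - rho2 / c2 - alpha * v


def task_aligned_assign(pred_boxes, pred_scores, gt_boxes, centers,
                        alpha=0.5, beta=6.0, topk=10):
    """YOLO-style task-aligned assignment for one image (pure numpy).

    Returns (assigned_gt index per anchor, -1 if background; target score)."""
    a = len(centers)
    assign = np.full(a, -1, dtype=int)
    tscore = np.zeros(a)
    m = len(gt_boxes)
    if m == 0:
        return assign, tscore
    in_box = ((centers[:, 0:1] > gt_boxes[None, :, 0]) &
              (centers[:, 0:1] < gt_boxes[None, :, 2]) &
              (centers[:, 1:2] > gt_boxes[None, :, 1]) &
              (centers[:, 1:2] < gt_boxes[None, :, 3]))          # (a, m)
    iou = iou_matrix(pred_boxes, gt_boxes)                       # (a, m)
    metric = (pred_scores[:, None] ** alpha) * (iou ** beta) * in_box
    selected = np.zeros_like(in_box)
    k = min(topk, a)
    for j in range(m):
        cand = np.argpartition(-metric[:, j], k - 1)[:k]
        cand = cand[metric[cand, j] > 0]
        selected[cand, j] = True
    # an anchor serving several boxes goes to the one with the best metric
    masked = np.where(selected, metric, -1.0)
    best = masked.argmax(axis=1)
    pos = masked.max(axis=1) > 0
    assign[pos] = best[pos]
    # soft targets: per-box normalisation of the alignment metric
    for j in range(m):
        sel = assign == j
        if not sel.any():
            continue
        mj = metric[sel, j]
        tscore[sel] = mj / (mj.max() + 1e-9) * iou[sel, j].max()
    return assign, tscore


def detection_loss(outputs, targets, cfg: TrainConfig, strides=(8, 16, 32)):
    """Composite loss for a batch.

    targets: list (len B) of (m_i, 4) xyxy arrays in input pixels.
    Returns (total loss Tensor, dict of float components).
    """
    hw = [(o[0].shape[2], o[0].shape[3]) for o in outputs]
    centers, stride_vec = _anchor_grid(hw, strides)
    b = outputs[0][0].shape[0]
    nc = outputs[0][1].shape[1]

    box_parts, cls_parts = [], []
    for (box_t, cls_t) in outputs:
        bb, _, h, w = box_t.shape
        box_parts.append(box_t.reshape(bb, 4 * DFL_BINS, h * w).transpose(0, 2, 1))
        cls_parts.append(cls_t.reshape(bb, nc, h * w).transpose(0, 2, 1))
    box_logits = Tensor.concat(box_parts, axis=1)    # (b, A, 64)
    cls_logits = Tensor.concat(cls_parts, axis=1)    # (b, A, nc)
    pred_boxes = _decode_boxes(box_logits, centers, stride_vec)

    with no_grad():
        scores_np = expit(cls_logits.data.max(axis=2))
        boxes_np = pred_boxes.data

    cls_target = np.zeros((b, cls_logits.shape[1], nc), dtype=np.float32)
    pos_b, pos_a, pos_gt, pos_w = [], [], [], []
    gt_per_pos = []
    for i in range(b):
        gt = np.asarray(targets[i], dtype=np.float64).reshape(-1, 4)
        assign, tscore = task_aligned_assign(boxes_np[i], scores_np[i], gt, centers)
        pos = np.nonzero(assign >= 0)[0]
        for a_idx in pos:
            pos_b.append(i)
            pos_a.append(a_idx)
            gt_per_pos.append(gt[assign[a_idx]])
            pos_w.append(tscore[a_idx])
        cls_target[i, pos, 0] = tscore[pos]

    target_sum = max(float(cls_target.sum()), 1.0)
    logits = cls_logits.clip(-15.0, 15.0)
    p = logits.sigmoid()
    tgt = Tensor(cls_target)
    eps = 1e-7
    bce = -(tgt * (p + eps).log() + (1.0 - tgt) * (1.0 - p + eps).log())
    cls_loss = bce.sum() / target_sum

    if pos_a:
        pos_b = np.array(pos_b)
        pos_a = np.array(pos_a)
        w = np.array(pos_w, dtype=np.float32)
        w_t = Tensor((w / max(w.sum(), 1e-9)).astype(np.float32))
        gt_arr = np.array(gt_per_pos)
        pb = pred_boxes[pos_b, pos_a]                      # (n,4)
        ciou = _ciou(pb, gt_arr)
        box_loss = ((1.0 - ciou) * w_t).sum()

        # DFL towards the two integer neighbours of the target distances
        sv = stride_vec[pos_a]
        tl = (centers[pos_a, 0] - gt_arr[:, 0]) / sv
        tt = (centers[pos_a, 1] - gt_arr[:, 1]) / sv
        tr = (gt_arr[:, 2] - centers[pos_a, 0]) / sv
        tb = (gt_arr[:, 3] - centers[pos_a, 1]) / sv
        tdist = np.clip(np.stack([tl, tt, tr, tb], axis=1), 0, DFL_BINS - 1 - 1e-3)
        lo = np.floor(tdist).astype(int)
        hi = lo + 1
        w_hi = (tdist - lo).astype(np.float32)
        w_lo = 1.0 - w_hi
        pos_logits = box_logits[pos_b, pos_a].reshape(len(pos_a), 4, DFL_BINS)
        logp = (pos_logits.softmax(axis=2) + eps).log()
        n_idx = np.repeat(np.arange(len(pos_a)), 4)
        s_idx = np.tile(np.arange(4), len(pos_a))
        nll = -(logp[n_idx, s_idx, lo.ravel()] * Tensor(w_lo.ravel())
                + logp[n_idx, s_idx, hi.ravel()] * Tensor(w_hi.ravel()))
        dfl_loss = (nll.reshape(len(pos_a), 4).mean(axis=1) * w_t).sum()
    else:
        box_loss = Tensor(0.0)
        dfl_loss = Tensor(0.0)

    total = cfg.box_gain * box_loss + cfg.cls_gain * cls_loss + cfg.dfl_gain * dfl_loss
    parts = {"box": float(box_loss.data), "cls": float(cls_loss.data),
             "dfl": float(dfl_loss.data), "total": float(total.data),
             "num_pos": len(pos_a)}
    return total, parts


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------
def _prepare(samples, imgsz):
    """Letterbox images and boxes to the training resolution."""
    out = []
    for img, ann in samples:
        boxed, p = letterbox(img, imgsz)
        x = boxed.transpose(2, 0, 1).astype(np.float32) / 255.0
        if ann.boxes:
            arr = np.array([b.xyxy for b in ann.boxes])
            arr[:, [0, 2]] = arr[:, [0, 2]] * p.scale + p.pad_x
            arr[:, [1, 3]] = arr[:, [1, 3]] * p.scale + p.pad_y
        else:
            arr = np.zeros((0, 4))
        out.append((x, arr))
    return out


def train(model: Detector, samples, cfg: TrainConfig, log_csv: str | None = None):
    """Optimize on (image, Annotation) pairs; returns per-epoch history.

    ``samples`` may also carry pre-letterboxed (chw float array, xyxy array)
    pairs. Raises on an empty training set.
    """
    if len(samples) == 0:
        raise ValueError("empty training split")
    if isinstance(samples[0][0], np.ndarray) and samples[0][0].ndim == 3 \
            and samples[0][0].shape[0] == 3 and samples[0][0].dtype == np.float32:
        data = list(samples)
    else:
        data = _prepare(samples, cfg.imgsz)

    rng = np.random.default_rng(cfg.seed)
    model.train()
    opt = SGD(model.trainable_parameters(), cfg.lr, cfg.momentum, cfg.weight_decay)
    history = []
    n = len(data)
    for epoch in range(cfg.epochs):
        # linear warmup over the first warmup_epochs
        if cfg.warmup_epochs and epoch < cfg.warmup_epochs:
            opt.lr = cfg.lr * (epoch + 1) / cfg.warmup_epochs
        else:
            opt.lr = cfg.lr
        order = rng.permutation(n)
        sums = {"box": 0.0, "cls": 0.0, "dfl": 0.0, "total": 0.0}
        n_batches = 0
        for s in range(0, n, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            xb = Tensor(np.stack([data[i][0] for i in idx]))
            tb = [data[i][1] for i in idx]
            outputs = model(xb)
            loss, parts = detection_loss(outputs, tb, cfg)
            opt.zero_grad()
            loss.backward()
            opt.step(cfg.grad_clip)
            for k in sums:
                sums[k] += parts[k]
            n_batches += 1
        row = {"epoch": epoch, "lr": opt.lr,
               **{k: v / n_batches for k, v in sums.items()}}
        history.append(row)
    if log_csv:
        with open(log_csv, "w", newline="") as f:
            writer = csv.DictWriter(f, fieldnames=list(history[0]))
            writer.writeheader()
            writer.writerows(history)
    return history


def evaluate_model(model: Detector, samples, imgsz: int | None = None,
                   iou_threshold: float = 0.5, conf_threshold: float = 0.25,
                   decode_conf: float = 0.001) -> DetectionMetrics:
    """Detection metrics of a model over (image, Annotation) pairs."""
    imgsz = imgsz or model.cfg.imgsz
    model.eval()
    predictions, gts = [], {}
    for i, (img, ann) in enumerate(samples):
        boxed, p = letterbox(img, imgsz)
        x = Tensor(boxed.transpose(2, 0, 1)[None].astype(np.float32) / 255.0)
        with no_grad():
            outputs = model(x)
        dets = decode_and_nms(outputs, decode_conf, 0.45,
                              letterbox_params=p, orig_size=(ann.width, ann.height))
        for d in dets:
            predictions.append((i, d.xyxy, d.score))
        gts[i] = np.array([b.xyxy for b in ann.boxes]).reshape(-1, 4)
    return evaluate_detections(predictions, gts, iou_threshold, conf_threshold)
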