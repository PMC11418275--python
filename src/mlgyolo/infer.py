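"""Raw head outputs -> boxes -> picking point.

The anchor-free head emits, per cell at strides 8/16/32, a 4x16-bin
distribution over box-side distances and class logits. Decoding takes the
softmax expectation of each distribution, scales by the stride around the
cell centre, filters by confidence and applies greedy IoU non-maximum
suppression with a deterministic tie-break (score, then area, then index).
The picking point of a detection is the arithmetic centre of its box.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from PIL import Image

from .blocks import DFL_BINS
from .boxes import BoundingBox, box_center, iou_matrix
from .tensor import Tensor, no_grad

__all__ = ["LetterboxParams", "letterbox", "unletterbox_boxes",
           "decode_raw", "nms", "decode_and_nms", "detect_image", "box_center"]


@dataclass
class LetterboxParams:
    scale: float
    pad_x: float
    pad_y: float
    out_w: int
    out_h: int


def letterbox(image: np.ndarray, size: int | tuple[int, int],
              fill: int = 114) -> tuple[np.ndarray, LetterboxParams]:
    """Aspect-preserving resize + pad to ``size`` (uint8 HWC image)."""
    oh, ow = (size, size) if isinstance(size, int) else size
    h, w = image.shape[:2]
    scale = min(ow / w, oh / h)
    nw, nh = int(round(w * scale)), int(round(h * scale))
    resized = np.asarray(Image.fromarray(image).resize((nw, nh), Image.BILINEAR))
    out = np.full((oh, ow, 3), fill, dtype=np.uint8)
    px, py = (ow - nw) // 2, (oh - nh) // 2
    out[py:py + nh, px:px + nw] = resized
    return out, LetterboxParams(scale, px, py, ow, oh)


def unletterbox_boxes(boxes: np.ndarray, p: LetterboxParams,
                      orig_w: int, orig_h: int) -> np.ndarray:
    """Map xyxy boxes from letterboxed to original image coordinates."""
    out = np.atleast_2d(np.asarray(boxes, dtype=np.float64)).copy()
    out[:, [0, 2]] = (out[:, [0, 2]] - p.pad_x) / p.scale
    out[:, [1, 3]] = (out[:, [1, 3]] - p.pad_y) / p.scale
    out[:, [0, 2]] = out[:, [0, 2]].clip(0, orig_w)
    out[:, [1, 3]] = out[:, [1, 3]].clip(0, orig_h)
    return out


def dfl_expectation(box_logits: np.ndarray) -> np.ndarray:
    """(B, 4*BINS, H, W) logits -> (B, 4, H*W) expected ltrb distances (cells)."""
    b, c, h, w = box_logits.shape
    x = box_logits.reshape(b, 4, DFL_BINS, h * w)
    x = x - x.max(axis=2, keepdims=True)
    e = np.exp(x)
    p = e / e.sum(axis=2, keepdims=True)
    bins = np.arange(DFL_BINS, dtype=np.float64).reshape(1, 1, -1, 1)
    return (p * bins).sum(axis=2)


def decode_raw(outputs, strides=(8, 16, 32)):
    """Multi-scale raw outputs -> (boxes xyxy (B,A,4), scores (B,A,nc)).

    Coordinates are in letterboxed-input pixels.
    """
    all_boxes, all_scores = [], []
    for (box_t, cls_t), stride in zip(outputs, strides):
        box = box_t.data if isinstance(box_t, Tensor) else np.asarray(box_t)
        cls = cls_t.data if isinstance(cls_t, Tensor) else np.asarray(cls_t)
        b, _, h, w = box.shape
        d = dfl_expectation(box) * stride                       # (b,4,hw)
        ys, xs = np.mgrid[0:h, 0:w]
        cx = (xs.ravel() + 0.5) * stride
        cy = (ys.ravel() + 0.5) * stride
        xyxy = np.stack([cx - d[:, 0], cy - d[:, 1], cx + d[:, 2], cy + d[:, 3]], axis=-1)
        score = expit(cls.reshape(b, cls.shape[1], h * w))
        all_boxes.append(xyxy)
        all_scores.append(score.transpose(0, 2, 1))
    return np.concatenate(all_boxes, axis=1), np.concatenate(all_scores, axis=1)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float = 0.45) -> np.ndarray:
    """Greedy NMS; returns kept indices. Ordering ties broken by
    (score desc, area desc, index asc), so the result is permutation-invariant."""
    boxes = np.atleast_2d(boxes)
    if len(boxes) == 0:
        return np.zeros(0, dtype=int)
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    idx = np.arange(len(boxes))
    order = np.lexsort((idx, -areas, -scores))
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        ious = iou_matrix(boxes[i], boxes[order])[0]
        suppressed[order[ious > iou_threshold]] = True
        suppressed[i] = False
    return np.array(sorted(keep, key=lambda j: (-scores[j], -areas[j], j)), dtype=int)


def decode_and_nms(outputs, conf_threshold: float = 0.25,
                   iou_threshold: float = 0.45, strides=(8, 16, 32),
                   letterbox_params: LetterboxParams | None = None,
                   orig_size: tuple[int, int] | None = None) -> list[BoundingBox]:
    """Raw outputs of one image -> final detections, in original-image pixels
    when letterbox parameters are provided."""
    boxes, scores = decode_raw(outputs, strides)
    boxes, scores = boxes[0], scores[0]
    cls_id = scores.argmax(axis=1)
    conf = scores[np.arange(len(scores)), cls_id]
    m = conf >= conf_threshold
    boxes, conf, cls_id = boxes[m], conf[m], cls_id[m]
    keep = nms(boxes, conf, iou_threshold)
    boxes, conf, cls_id = boxes[keep], conf[keep], cls_id[keep]
    if letterbox_params is not None and orig_size is not None:
        ow, oh = orig_size
        boxes = unletterbox_boxes(boxes, letterbox_params, ow, oh) if len(boxes) else boxes
        lim_w, lim_h = ow, oh
    else:
        lim_w = letterbox_params.out_w if letterbox_params else None
        lim_h = letterbox_params.out_h if letterbox_params else None
    out = []
    for b, s, c in zip(boxes, conf, cls_id):
        bb = BoundingBox(*b, score=float(s), cls=int(c))
        if lim_w is not None:
            bb = bb.clipped(lim_w, lim_h)
        out.append(bb)
    return out


def detect_image(model, image: np.ndarray, imgsz: int | None = None,
                 conf_threshold: float = 0.25, iou_threshold: float = 0.45
                 ) -> list[BoundingBox]:
    """Full single-image pipeline: letterbox, forward, decode, NMS, un-letterbox."""
    imgsz = imgsz or model.cfg.imgsz
    boxed, p = letterbox(image, imgsz)
    x = Tensor(boxed.transpose(2, 0, 1)[None].astype(np.float32) / 255.0)
    model.eval()
    with no_grad():
        outputs = model(x)
    h, w = image.shape[:2]
    return decode_and_nms(outputs, conf_threshold, iou_threshold,
                          letterbox_params=p, orig_size=(w, h))
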