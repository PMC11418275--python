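"""Bounding-box containers and geometry shared across modules."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BoundingBox", "box_center", "iou_matrix", "xyxy_to_yolo",
           "yolo_to_xyxy", "mirror_boxes", "translate_boxes", "rotate_boxes"]


@dataclass
class BoundingBox:
    """Axis-aligned box in pixel coordinates with detection score."""
    xmin: float
    ymin: float
    xmax: float
    ymax: float
    score: float = 1.0
    cls: int = 0

    def __post_init__(self):
        if self.xmin > self.xmax or self.ymin > self.ymax:
            raise ValueError("box corners out of order")

    @property
    def xyxy(self) -> np.ndarray:
        return np.array([self.xmin, self.ymin, self.xmax, self.ymax], dtype=np.float64)

    @property
    def area(self) -> float:
        return max(self.xmax - self.xmin, 0.0) * max(self.ymax - self.ymin, 0.0)

    def clipped(self, width: int, height: int) -> "BoundingBox":
        return BoundingBox(
            min(max(self.xmin, 0.0), width), min(max(self.ymin, 0.0), height),
            min(max(self.xmax, 0.0), width), min(max(self.ymax, 0.0), height),
            self.score, self.cls)


def box_center(b: BoundingBox | np.ndarray) -> tuple[float, float]:
    """Arithmetic midpoint of a box: ((xmin+xmax)/2, (ymin+ymax)/2)."""
    if isinstance(b, BoundingBox):
        return ((b.xmin + b.xmax) / 2.0, (b.ymin + b.ymax) / 2.0)
    b = np.asarray(b, dtype=np.float64)
    return (float(b[0] + b[2]) / 2.0, float(b[1] + b[3]) / 2.0)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of two (n,4) / (m,4) xyxy arrays -> (n,m)."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def xyxy_to_yolo(boxes: np.ndarray, width: int, height: int) -> np.ndarray:
    """Pixel xyxy -> normalized (xc, yc, w, h) rows."""
    boxes = np.atleast_2d(np.asarray(boxes, dtype=np.float64))
    xc = (boxes[:, 0] + boxes[:, 2]) / 2.0 / width
    yc = (boxes[:, 1] + boxes[:, 3]) / 2.0 / height
    w = (boxes[:, 2] - boxes[:, 0]) / width
    h = (boxes[:, 3] - boxes[:, 1]) / height
    return np.stack([xc, yc, w, h], axis=1)


def yolo_to_xyxy(rows: np.ndarray, width: int, height: int) -> np.ndarray:
    rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
    xc, yc, w, h = rows[:, 0] * width, rows[:, 1] * height, rows[:, 2] * width, rows[:, 3] * height
    return np.stack([xc - w / 2, yc - h / 2, xc + w / 2, yc + h / 2], axis=1)


def mirror_boxes(boxes: np.ndarray, width: int) -> np.ndarray:
    """Horizontal mirror: x' = width - x (corners re-ordered)."""
    boxes = np.atleast_2d(np.asarray(boxes, dtype=np.float64)).copy()
    x0 = width - boxes[:, 2]
    x1 = width - boxes[:, 0]
    boxes[:, 0], boxes[:, 2] = x0, x1
    return boxes


def translate_boxes(boxes: np.ndarray, dx: float, dy: float,
                    width: int, height: int) -> np.ndarray:
    """Shift boxes, clip to the frame, drop boxes that leave it entirely."""
    boxes = np.atleast_2d(np.asarray(boxes, dtype=np.float64)).copy()
    boxes[:, [0, 2]] += dx
    boxes[:, [1, 3]] += dy
    boxes[:, [0, 2]] = boxes[:, [0, 2]].clip(0, width)
    boxes[:, [1, 3]] = boxes[:, [1, 3]].clip(0, height)
    keep = (boxes[:, 2] > boxes[:, 0]) & (boxes[:, 3] > boxes[:, 1])
    return boxes[keep]


def rotate_boxes(boxes: np.ndarray, angle_deg: float,
                 width: int, height: int) -> np.ndarray:
    """Rotate corners about the image centre, take the axis-aligned hull, clip."""
    boxes = np.atleast_2d(np.asarray(boxes, dtype=np.float64))
    if boxes.size == 0:
        return boxes.reshape(0, 4)
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    cx, cy = width / 2.0, height / 2.0
    corners = np.stack([
        boxes[:, [0, 1]], boxes[:, [2, 1]], boxes[:, [0, 3]], boxes[:, [2, 3]],
    ], axis=1)  # (n,4,2)
    rel = corners - [cx, cy]
    rot = np.empty_like(rel)
    rot[..., 0] = c * rel[..., 0] - s * rel[..., 1]
    rot[..., 1] = s * rel[..., 0] + c * rel[..., 1]
    rot += [cx, cy]
    out = np.stack([rot[..., 0].min(1), rot[..., 1].min(1),
                    rot[..., 0].max(1), rot[..., 1].max(1)], axis=1)
    out[:, [0, 2]] = out[:, [0, 2]].clip(0, width)
    out[:, [1, 3]] = out[:, [1, 3]].clip(0, height)
    keep = (out[:, 2] > out[:, 0]) & (out[:, 3] > out[:, 1])
    return out[keep]
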