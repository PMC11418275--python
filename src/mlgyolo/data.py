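"""Synthetic orchard scenes with ground-truth boxes.

Real winter-jujube imagery is 640x480 RGB with many small, quasi-spherical
fruit partially hidden by foliage under variable daylight. The generator
emulates those statistics — textured background, shaded elliptical fruit,
elongated leaf-shaped occluders, a global illumination factor — so the whole
detection/localization pipeline can be exercised and tested without the
deposited dataset. A fruit is annotated when at least ``visibility_threshold``
of its area remains visible after all later fruit and opaque leaves are drawn.

Also here: the dataset arithmetic (random 8:1:1 split expanded threefold by
augmented copies) and YOLO-format label round-tripping.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter

from .boxes import (BoundingBox, mirror_boxes, rotate_boxes, translate_boxes,
                    xyxy_to_yolo, yolo_to_xyxy)

__all__ = ["SceneSpec", "Annotation", "generate_scene", "augment",
           "split_and_triple", "build_dataset", "load_dataset",
           "write_yolo_labels", "read_yolo_labels"]


@dataclass
class SceneSpec:
    """Parameters of one synthetic orchard image. The seed fixes everything."""
    width: int = 640
    height: int = 480
    fruit_count: tuple[int, int] = (4, 12)
    fruit_radius: tuple[float, float] = (12.0, 26.0)   # px, small vs the frame
    leaf_count: tuple[int, int] = (6, 16)
    leaf_opacity: float = 1.0
    illumination: tuple[float, float] = (0.7, 1.3)
    visibility_threshold: float = 0.25
    seed: int = 0

    def __post_init__(self):
        for name in ("fruit_count", "fruit_radius", "leaf_count", "illumination"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} range is empty")


@dataclass
class Annotation:
    image_id: str
    boxes: list[BoundingBox]
    width: int
    height: int

    def to_yolo_lines(self) -> list[str]:
        if not self.boxes:
            return []
        arr = np.array([b.xyxy for b in self.boxes])
        rows = xyxy_to_yolo(arr, self.width, self.height)
        return [f"{b.cls} {r[0]:.6f} {r[1]:.6f} {r[2]:.6f} {r[3]:.6f}"
                for b, r in zip(self.boxes, rows)]

    @classmethod
    def from_yolo_lines(cls, image_id, lines, width, height) -> "Annotation":
        boxes = []
        for ln in lines:
            parts = ln.split()
            if not parts:
                continue
            c = int(parts[0])
            xyxy = yolo_to_xyxy(np.array([[float(v) for v in parts[1:5]]]), width, height)[0]
            boxes.append(BoundingBox(*xyxy, score=1.0, cls=c))
        return cls(image_id, boxes, width, height)


def _ellipse_mask(h, w, cx, cy, rx, ry, theta):
    yy, xx = np.mgrid[0:h, 0:w]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, Annotation]:
    """Render one scene. Returns (uint8 HxWx3 image, Annotation)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # cluttered green-brown background: smoothed noise in two colour planes
    base = gaussian_filter(rng.standard_normal((h, w)), sigma=12)
    fine = gaussian_filter(rng.standard_normal((h, w)), sigma=2)
    tex = (base - base.min()) / (np.ptp(base) + 1e-9)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[..., 0] = 0.18 + 0.12 * tex + 0.03 * fine
    img[..., 1] = 0.28 + 0.18 * tex + 0.04 * fine
    img[..., 2] = 0.10 + 0.08 * tex + 0.02 * fine

    n_fruit = int(rng.integers(spec.fruit_count[0], spec.fruit_count[1] + 1))
    fruit_params = []
    for _ in range(n_fruit):
        r = rng.uniform(*spec.fruit_radius)
        rx, ry = r, r * rng.uniform(0.75, 1.0)           # quasi-elliptical jujube
        cx = rng.uniform(rx, w - rx)
        cy = rng.uniform(ry, h - ry)
        theta = rng.uniform(0, np.pi)
        fruit_params.append((cx, cy, rx, ry, theta))

    # visibility bookkeeping: per-fruit total and currently-visible pixel counts
    owner = np.full((h, w), -1, dtype=np.int32)
    totals = np.zeros(n_fruit)
    yy, xx = np.mgrid[0:h, 0:w]
    for i, (cx, cy, rx, ry, theta) in enumerate(fruit_params):
        mask = _ellipse_mask(h, w, cx, cy, rx, ry, theta)
        totals[i] = mask.sum()
        owner[mask] = i                                   # later fruit draw on top
        # shaded fruit: red-brown body, radial shading, small specular spot
        ct, st = np.cos(theta), np.sin(theta)
        u = ((xx - cx) * ct + (yy - cy) * st) / max(rx, 1e-6)
        v = (-(xx - cx) * st + (yy - cy) * ct) / max(ry, 1e-6)
        rad2 = np.where(mask, u ** 2 + v ** 2, 1.0)
        shade = np.sqrt(np.clip(1.0 - rad2, 0.0, 1.0))
        hue = rng.uniform(0.35, 0.75)                     # ripeness: green -> red
        color = np.array([0.45 + 0.4 * hue, 0.55 - 0.25 * hue, 0.12])
        spot = np.exp(-(((u + 0.35) ** 2 + (v + 0.35) ** 2) / 0.08))
        for c in range(3):
            body = color[c] * (0.45 + 0.55 * shade) + 0.35 * spot
            img[..., c] = np.where(mask, body, img[..., c])

    n_leaf = int(rng.integers(spec.leaf_count[0], spec.leaf_count[1] + 1))
    for _ in range(n_leaf):
        # leaves prefer to sit near a fruit so occlusion actually happens
        if n_fruit and rng.uniform() < 0.7:
            fi = int(rng.integers(n_fruit))
            cx = fruit_params[fi][0] + rng.normal(0, spec.fruit_radius[1])
            cy = fruit_params[fi][1] + rng.normal(0, spec.fruit_radius[1])
        else:
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        length = rng.uniform(1.2, 3.0) * spec.fruit_radius[1]
        width_ = length * rng.uniform(0.25, 0.45)
        theta = rng.uniform(0, np.pi)
        mask = _ellipse_mask(h, w, cx, cy, length, width_, theta)
        green = np.array([0.12, 0.45, 0.10]) * rng.uniform(0.7, 1.3)
        a = spec.leaf_opacity
        for c in range(3):
            img[..., c] = np.where(mask, (1 - a) * img[..., c] + a * green[c], img[..., c])
        if a > 0.5:                                        # opaque enough to occlude
            owner[mask] = -1

    boxes = []
    for i, (cx, cy, rx, ry, theta) in enumerate(fruit_params):
        visible = (owner == i).sum()
        if totals[i] == 0 or visible / totals[i] < spec.visibility_threshold:
            continue
        half_w = np.hypot(rx * np.cos(theta), ry * np.sin(theta))
        half_h = np.hypot(rx * np.sin(theta), ry * np.cos(theta))
        b = BoundingBox(cx - half_w, cy - half_h, cx + half_w, cy + half_h, 1.0, 0)
        boxes.append(b.clipped(w, h))

    img *= rng.uniform(*spec.illumination)
    img8 = (np.clip(img, 0, 1) * 255).astype(np.uint8)
    return img8, Annotation(f"scene_{spec.seed}", boxes, w, h)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------
def augment(image: np.ndarray, ann: Annotation, op: str, **params
            ) -> tuple[np.ndarray, Annotation]:
    """Apply one photometric/geometric augmentation consistently to boxes.

    ops: ``brightness(factor)``, ``translation(dx, dy)``, ``mirror()``,
    ``rotation(angle)`` (degrees, about the image centre; boxes become the
    axis-aligned hull of their rotated corners). Boxes that leave the frame
    entirely are dropped.
    """
    h, w = image.shape[:2]
    arr = np.array([b.xyxy for b in ann.boxes]).reshape(-1, 4)
    if op == "brightness":
        factor = params.get("factor", 1.2)
        out = np.clip(image.astype(np.float64) * factor, 0, 255).astype(np.uint8)
        new = arr
    elif op == "mirror":
        out = image[:, ::-1].copy()
        new = mirror_boxes(arr, w)
    elif op == "translation":
        dx, dy = int(params.get("dx", 0)), int(params.get("dy", 0))
        out = np.zeros_like(image)
        src = image[max(0, -dy):h - max(0, dy), max(0, -dx):w - max(0, dx)]
        out[max(0, dy):max(0, dy) + src.shape[0], max(0, dx):max(0, dx) + src.shape[1]] = src
        new = translate_boxes(arr, dx, dy, w, h)
    elif op == "rotation":
        angle = params.get("angle", 10.0)
        pil = Image.fromarray(image).rotate(-angle, resample=Image.BILINEAR)
        out = np.asarray(pil)
        new = rotate_boxes(arr, angle, w, h)
    else:
        raise ValueError(f"unknown augmentation {op!r}")
    boxes = [BoundingBox(*b, score=1.0, cls=0) for b in new]
    return out, Annotation(ann.image_id + f"_{op}", boxes, w, h)


def _random_augment(image, ann, rng):
    op = rng.choice(["brightness", "translation", "mirror", "rotation"])
    if op == "brightness":
        return augment(image, ann, op, factor=rng.uniform(0.7, 1.3))
    if op == "translation":
        return augment(image, ann, op, dx=int(rng.uniform(-0.1, 0.1) * ann.width),
                       dy=int(rng.uniform(-0.1, 0.1) * ann.height))
    if op == "rotation":
        return augment(image, ann, op, angle=rng.uniform(-15, 15))
    return augment(image, ann, op)


# ---------------------------------------------------------------------------
# split arithmetic
# ---------------------------------------------------------------------------
def split_and_triple(n_images: int, ratio=(0.8, 0.1, 0.1),
                     augmentations_per_image: int = 2, seed: int = 0,
                     augment_val_test: bool = True):
    """Random 8:1:1-style partition expanded by augmented copies.

    Returns three lists of (source_index, copy_index); copy 0 is the original
    image, copies >= 1 are augmented duplicates. Sizes use largest-remainder
    rounding. Augmented copies stay in their source's split, so no content
    leaks across splits. With ``augment_val_test=False`` only the training
    split is expanded.
    """
    if abs(sum(ratio) - 1.0) > 1e-9:
        raise ValueError("split ratio must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_images)
    exact = np.array(ratio, dtype=np.float64) * n_images
    sizes = np.floor(exact).astype(int)
    rem = n_images - sizes.sum()
    for i in np.argsort(-(exact - sizes))[:rem]:
        sizes[i] += 1
    bounds = np.cumsum(sizes)
    groups = np.split(order, bounds[:-1])
    out = []
    for gi, g in enumerate(groups):
        expand = augment_val_test or gi == 0
        copies = range(1 + augmentations_per_image) if expand else range(1)
        out.append([(int(i), int(c)) for i in sorted(g) for c in copies])
    return tuple(out)


# ---------------------------------------------------------------------------
# dataset IO
# ---------------------------------------------------------------------------
def write_yolo_labels(path: str, ann: Annotation):
    with open(path, "w") as f:
        f.write("\n".join(ann.to_yolo_lines()) + ("\n" if ann.boxes else ""))


def read_yolo_labels(path: str, image_id: str, width: int, height: int) -> Annotation:
    with open(path) as f:
        return Annotation.from_yolo_lines(image_id, f.read().splitlines(), width, height)


def make_samples(n_images: int, spec: SceneSpec | None = None, seed: int = 0,
                 augmentations_per_image: int = 0):
    """In-memory dataset: list of (image, Annotation); seeds derive from `seed`."""
    spec = spec or SceneSpec()
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_images):
        s = replace(spec, seed=int(rng.integers(0, 2 ** 31 - 1)))
        img, ann = generate_scene(s)
        samples.append((img, ann))
        for _ in range(augmentations_per_image):
            samples.append(_random_augment(img, ann, rng))
    return samples


def build_dataset(out_dir: str, n_images: int, spec: SceneSpec | None = None,
                  seed: int = 0, augmentations_per_image: int = 2,
                  ratio=(0.8, 0.1, 0.1), augment_val_test: bool = True) -> str:
    """Render a dataset to disk (PNG + YOLO labels) and write its manifest."""
    spec = spec or SceneSpec()
    rng = np.random.default_rng(seed)
    img_dir = os.path.join(out_dir, "images")
    lbl_dir = os.path.join(out_dir, "labels")
    os.makedirs(img_dir, exist_ok=True)
    os.makedirs(lbl_dir, exist_ok=True)

    base = []
    for i in range(n_images):
        s = replace(spec, seed=int(rng.integers(0, 2 ** 31 - 1)))
        base.append(generate_scene(s))

    splits = split_and_triple(n_images, ratio, augmentations_per_image, seed,
                              augment_val_test)
    manifest = {"seed": seed, "n_source_images": n_images,
                "image_size": [spec.width, spec.height],
                "names": {0: "winter jujube"}, "splits": {}}
    aug_rng = np.random.default_rng(seed + 1)
    for name, entries in zip(("train", "val", "test"), splits):
        files = []
        for src, copy in entries:
            img, ann = base[src]
            if copy > 0:
                img, ann = _random_augment(img, ann, aug_rng)
            stem = f"{name}_{src:05d}_{copy}"
            Image.fromarray(img).save(os.path.join(img_dir, stem + ".png"))
            write_yolo_labels(os.path.join(lbl_dir, stem + ".txt"),
                              Annotation(stem, ann.boxes, ann.width, ann.height))
            files.append(stem)
        manifest["splits"][name] = files
    mpath = os.path.join(out_dir, "manifest.yaml")
    with open(mpath, "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=False)
    return mpath


def load_dataset(manifest_path: str, split: str = "train"):
    """Read (image, Annotation) pairs listed in a manifest split."""
    root = os.path.dirname(manifest_path)
    with open(manifest_path) as f:
        manifest = yaml.safe_load(f)
    w, h = manifest["image_size"]
    out = []
    for stem in manifest["splits"][split]:
        img = np.asarray(Image.open(os.path.join(root, "images", stem + ".png")))
        ann = read_yolo_labels(os.path.join(root, "labels", stem + ".txt"), stem, w, h)
        out.append((img, ann))
    return out
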