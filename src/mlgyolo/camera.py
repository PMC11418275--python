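"""Pinhole deprojection and hand-eye coordinate transforms.

A detection's centre pixel plus its depth reading is deprojected through the
camera intrinsics into the camera frame, then carried into the robot base
frame by the rigid transform from an eye-to-hand calibration, given as a
unit quaternion (qw, qx, qy, qz) and a translation vector. The quaternion is
expanded to a rotation matrix as

    R = [[1-2qy^2-2qz^2, 2qxqy-2qzqw,  2qxqz+2qyqw],
         [2qxqy+2qzqw,  1-2qx^2-2qz^2, 2qyqz-2qxqw],
         [2qxqz-2qyqw,  2qyqz+2qxqw,  1-2qx^2-2qy^2]]

and combined with t into the 4x4 affine transform T = [[R, t], [0, 1]]
applied to homogeneous coordinates.

Depth maps are in millimetres (depth-camera convention); calibration
translation units are recorded explicitly and converted at the interface.
A missing or non-positive depth at the centre pixel optionally falls back to
the median of the valid readings in the surrounding 5x5 patch.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .boxes import BoundingBox, box_center

__all__ = ["CameraIntrinsics", "HandEyeCalibration", "Point3D",
           "deproject", "depth_at", "quat_to_rotation", "assemble_affine",
           "camera_to_base", "locate_fruit", "SimulatedRGBDCamera"]

_UNIT_MM = {"mm": 1.0, "m": 1000.0}


@dataclass
class CameraIntrinsics:
    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    def to_yaml(self) -> str:
        return yaml.safe_dump({"fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy})

    @classmethod
    def from_yaml(cls, text: str) -> "CameraIntrinsics":
        return cls(**yaml.safe_load(text))


@dataclass
class HandEyeCalibration:
    """Camera -> robot-base rigid transform from an eye-to-hand calibration."""
    quaternion: tuple[float, float, float, float]   # (qw, qx, qy, qz)
    translation: tuple[float, float, float]
    unit: str = "m"

    def __post_init__(self):
        if self.unit not in _UNIT_MM:
            raise ValueError(f"unit must be one of {sorted(_UNIT_MM)}")
        q = np.asarray(self.quaternion, dtype=np.float64)
        n = np.linalg.norm(q)
        if n < 1e-8:
            raise ValueError("quaternion norm too small")
        self.quaternion = tuple(q / n)

    @property
    def transform_mm(self) -> np.ndarray:
        """4x4 camera->base transform with translation in millimetres."""
        r = quat_to_rotation(self.quaternion)
        t = np.asarray(self.translation, dtype=np.float64) * _UNIT_MM[self.unit]
        return assemble_affine(r, t)

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "quaternion": {k: float(v) for k, v in zip("qw qx qy qz".split(), self.quaternion)},
            "translation": {k: float(v) for k, v in zip("tx ty tz".split(), self.translation)},
            "unit": self.unit}, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "HandEyeCalibration":
        d = yaml.safe_load(text)
        q = d["quaternion"]
        t = d["translation"]
        return cls((q["qw"], q["qx"], q["qy"], q["qz"]),
                   (t["tx"], t["ty"], t["tz"]), d.get("unit", "m"))


@dataclass
class Point3D:
    x: float
    y: float
    z: float
    frame: str = "camera"    # 'camera' or 'base'

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=np.float64)

    @property
    def homogeneous(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z, 1.0], dtype=np.float64)


def quat_to_rotation(q) -> np.ndarray:
    """Unit-quaternion (qw,qx,qy,qz) -> 3x3 rotation matrix (det +1)."""
    q = np.asarray(q, dtype=np.float64)
    n = np.linalg.norm(q)
    if n < 1e-8:
        raise ValueError("quaternion norm too small to normalize")
    qw, qx, qy, qz = q / n
    return np.array([
        [1 - 2 * qy ** 2 - 2 * qz ** 2, 2 * qx * qy - 2 * qz * qw, 2 * qx * qz + 2 * qy * qw],
        [2 * qx * qy + 2 * qz * qw, 1 - 2 * qx ** 2 - 2 * qz ** 2, 2 * qy * qz - 2 * qx * qw],
        [2 * qx * qz - 2 * qy * qw, 2 * qy * qz + 2 * qx * qw, 1 - 2 * qx ** 2 - 2 * qy ** 2],
    ])


def assemble_affine(r: np.ndarray, t) -> np.ndarray:
    """Rotation + translation -> 4x4 homogeneous transform [[R, t], [0, 1]]."""
    out = np.eye(4)
    out[:3, :3] = np.asarray(r, dtype=np.float64)
    out[:3, 3] = np.asarray(t, dtype=np.float64)
    return out


def deproject(u: float, v: float, depth: float, k: CameraIntrinsics) -> Point3D:
    """Pixel (u, v) + range -> camera-frame point (pinhole model)."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    x = (u - k.cx) * depth / k.fx
    y = (v - k.cy) * depth / k.fy
    return Point3D(x, y, depth, frame="camera")


def depth_at(depth_map: np.ndarray, u: float, v: float,
             fallback_patch: int | None = 5) -> float:
    """Depth reading at a pixel; non-positive readings fall back to the
    median of valid values in the surrounding patch (None disables)."""
    h, w = depth_map.shape
    ui, vi = int(round(u)), int(round(v))
    if not (0 <= ui < w and 0 <= vi < h):
        raise ValueError(f"pixel ({u:.1f}, {v:.1f}) outside the {w}x{h} depth map")
    d = float(depth_map[vi, ui])
    if d > 0:
        return d
    if fallback_patch is None:
        return 0.0
    r = fallback_patch // 2
    patch = depth_map[max(0, vi - r):vi + r + 1, max(0, ui - r):ui + r + 1]
    valid = patch[patch > 0]
    return float(np.median(valid)) if valid.size else 0.0


def camera_to_base(p: Point3D, transform: np.ndarray) -> Point3D:
    """Apply the 4x4 camera->base transform to a camera-frame point."""
    if p.frame != "camera":
        raise ValueError(f"expected a camera-frame point, got frame={p.frame!r}")
    out = np.asarray(transform, dtype=np.float64) @ p.homogeneous
    out = out[:3] / out[3]
    return Point3D(*out, frame="base")


def locate_fruit(detections, depth_map: np.ndarray, k: CameraIntrinsics,
                 calib: HandEyeCalibration, rgb_shape=None,
                 fallback_patch: int | None = 5):
    """Detections + aligned depth -> base-frame points (mm).

    Returns (points, failures); detections whose depth is missing even after
    the patch fallback are reported in ``failures`` rather than dropped
    silently. ``rgb_shape`` (h, w), when given, must match the depth map.
    """
    if rgb_shape is not None and tuple(rgb_shape[:2]) != depth_map.shape:
        raise ValueError(f"RGB {tuple(rgb_shape[:2])} and depth {depth_map.shape} misaligned")
    transform = calib.transform_mm
    points, failures = [], []
    for det in detections:
        u, v = box_center(det)
        d = depth_at(depth_map, u, v, fallback_patch)
        if d <= 0:
            failures.append(det)
            continue
        points.append(camera_to_base(deproject(u, v, d, k), transform))
    return points, failures


class SimulatedRGBDCamera:
    """Render-then-invert oracle: project known base-frame fruit into an
    RGB-D view so the localization chain can be validated end to end."""

    def __init__(self, k: CameraIntrinsics, calib: HandEyeCalibration,
                 width: int = 640, height: int = 480):
        self.k, self.calib = k, calib
        self.width, self.height = width, height
        self.base_to_camera = np.linalg.inv(calib.transform_mm)

    def project(self, p_base_mm) -> tuple[float, float, float]:
        """Base-frame point (mm) -> (u, v, depth_mm)."""
        p = np.asarray(p_base_mm, dtype=np.float64)
        cam = self.base_to_camera @ np.append(p, 1.0)
        x, y, z = cam[:3]
        if z <= 0:
            raise ValueError("point behind the camera")
        return (self.k.fx * x / z + self.k.cx, self.k.fy * y / z + self.k.cy, z)

    def random_visible_points(self, n: int, rng: np.random.Generator,
                              depth_range_mm=(300.0, 1500.0), margin_px: int = 20
                              ) -> np.ndarray:
        """Sample base-frame fruit positions guaranteed to be in view."""
        t = self.calib.transform_mm
        pts = []
        for _ in range(n):
            u = rng.uniform(margin_px, self.width - margin_px)
            v = rng.uniform(margin_px, self.height - margin_px)
            z = rng.uniform(*depth_range_mm)
            cam = deproject(u, v, z, self.k).homogeneous
            pts.append((t @ cam)[:3])
        return np.array(pts)

    def render(self, fruit_base_mm, radius_px: int = 6, noise_sigma_mm: float = 0.0,
               rng: np.random.Generator | None = None):
        """Depth map (mm) + detections for fruit at known base positions."""
        depth = np.zeros((self.height, self.width), dtype=np.float64)
        dets = []
        order = sorted(fruit_base_mm, key=lambda p: -self.project(p)[2])
        for p in order:                       # far to near: nearer overwrites
            u, v, z = self.project(p)
            if noise_sigma_mm and rng is not None:
                z = z + rng.normal(0.0, noise_sigma_mm)
            yy, xx = np.mgrid[0:self.height, 0:self.width]
            disc = (xx - u) ** 2 + (yy - v) ** 2 <= radius_px ** 2
            depth[disc] = z
            dets.append(BoundingBox(u - radius_px, v - radius_px,
                                    u + radius_px, v + radius_px, 1.0, 0))
        return depth, dets
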