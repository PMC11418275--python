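"""3D localization: detection centres + depth -> robot base frame.

A simulated RGB-D camera with a known hand-eye calibration (quaternion +
translation) projects fruit at known base-frame positions into pixels and a
depth map. The localization chain — box centre, pinhole deprojection,
quaternion-to-rotation, 4x4 affine transform — recovers those positions. With
exact depth the recovery is numerically exact; with Gaussian depth noise the
per-axis mean absolute error and standard error behave like the folded
normal of the propagated noise.
"""
import numpy as np

from mlgyolo import CameraIntrinsics, HandEyeCalibration, locate_fruit, localization_errors
from mlgyolo.camera import SimulatedRGBDCamera

k = CameraIntrinsics(fx=615.0, fy=615.0, cx=320.0, cy=240.0)
calib = HandEyeCalibration(quaternion=(0.9238795, 0.0, 0.0, 0.3826834),  # 45 deg about z
                           translation=(0.40, -0.15, 0.55), unit="m")
cam = SimulatedRGBDCamera(k, calib)

rng = np.random.default_rng(0)
true_points = cam.random_visible_points(10, rng, depth_range_mm=(400, 1200))

# noise-free recovery
depth, dets = cam.render(true_points, radius_px=5)
points, failures = locate_fruit(dets, depth, k, calib)
by_depth = sorted(true_points, key=lambda p: -cam.project(p)[2])
exact_err = max(np.abs(p.xyz - q).max() for p, q in zip(points, by_depth))
print(f"noise-free recovery of 10 fruit: max |error| = {exact_err:.2e} mm, "
      f"{len(failures)} invalid-depth detections")

# with depth noise: summarise per-axis errors the way a positioning test would
sigma = 5.0
errors = []
for _ in range(200):
    p = cam.random_visible_points(1, rng)[0]
    u, v, z = cam.project(p)
    noisy_depth = np.full((cam.height, cam.width), z + rng.normal(0, sigma))
    from mlgyolo.boxes import BoundingBox
    det = BoundingBox(u - 4, v - 4, u + 4, v + 4)
    rec, _ = locate_fruit([det], noisy_depth, k, calib)
    errors.append(rec[0].xyz - p)
report = localization_errors(np.array(errors))
print(f"with {sigma:.0f} mm depth noise over n={report.n} measurements:")
for axis, d, se in zip("XYZ", report.mean_abs, report.standard_error):
    print(f"  {axis}: mean |error| {d:5.2f} mm   standard error {se:4.2f} mm")
print("(axial errors track sigma*sqrt(2/pi) ~ %.2f mm; lateral ones are smaller)"
      % (sigma * np.sqrt(2 / np.pi)))
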