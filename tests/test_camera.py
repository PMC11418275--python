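"""Pinhole deprojection, quaternion/affine transforms, end-to-end recovery."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mlgyolo.camera import (CameraIntrinsics, HandEyeCalibration, Point3D,
                            SimulatedRGBDCamera, assemble_affine,
                            camera_to_base, deproject, depth_at, locate_fruit,
                            quat_to_rotation)


def test_deproject_principal_point():
    k = CameraIntrinsics(500, 500, 320, 240)
    p = deproject(320, 240, 1.0, k)
    assert (p.x, p.y, p.z) == (0.0, 0.0, 1.0)
    assert p.frame == "camera"


def test_deproject_unit_intrinsics():
    k = CameraIntrinsics(1, 1, 0, 0)
    p = deproject(2, 3, 1.0, k)
    assert (p.x, p.y, p.z) == (2.0, 3.0, 1.0)


def test_deproject_linear_in_depth():
    k = CameraIntrinsics(600, 650, 311, 245)
    a = deproject(100, 50, 400.0, k)
    b = deproject(100, 50, 800.0, k)
    assert (b.x, b.y) == pytest.approx((2 * a.x, 2 * a.y))


def test_deproject_rejects_nonpositive_depth():
    with pytest.raises(ValueError):
        deproject(1, 1, 0.0, CameraIntrinsics(1, 1, 0, 0))


def test_quaternion_identity_and_half_turn():
    np.testing.assert_allclose(quat_to_rotation((1, 0, 0, 0)), np.eye(3))
    np.testing.assert_allclose(quat_to_rotation((0, 0, 0, 1)),
                               np.diag([-1.0, -1.0, 1.0]), atol=1e-15)


def test_quaternion_quarter_turn_about_z():
    q = (np.sqrt(2) / 2, 0, 0, np.sqrt(2) / 2)
    expected = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
    np.testing.assert_allclose(quat_to_rotation(q), expected, atol=1e-12)


def test_quaternion_near_zero_norm_rejected():
    with pytest.raises(ValueError):
        quat_to_rotation((1e-12, 0, 0, 0))


@settings(derandomize=True, max_examples=50)
@given(seed=st.integers(0, 10_000))
def test_quaternion_rotation_properties(seed):
    rng = np.random.default_rng(seed)
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    r = quat_to_rotation(q)
    np.testing.assert_allclose(r.T @ r, np.eye(3), atol=1e-10)
    assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(quat_to_rotation(-q), r, atol=1e-12)  # double cover


def test_assemble_affine_identity_and_translation():
    t = assemble_affine(np.eye(3), np.zeros(3))
    np.testing.assert_array_equal(t, np.eye(4))
    t = assemble_affine(np.eye(3), [1, 2, 3])
    p = t @ np.array([5.0, 5, 5, 1])
    np.testing.assert_allclose(p[:3], [6, 7, 8])
    np.testing.assert_array_equal(t[3], [0, 0, 0, 1])


def test_affine_inverse_roundtrip():
    q = np.array([0.6, 0.1, -0.5, 0.3])
    r = quat_to_rotation(q)
    t = assemble_affine(r, [4.0, -2.0, 9.0])
    inv = assemble_affine(r.T, -r.T @ np.array([4.0, -2.0, 9.0]))  # closed form
    np.testing.assert_allclose(t @ inv, np.eye(4), atol=1e-12)


def test_camera_to_base_identity_retags():
    p = camera_to_base(Point3D(1, 2, 3, "camera"), np.eye(4))
    assert p.frame == "base" and (p.x, p.y, p.z) == (1, 2, 3)


def test_camera_to_base_pure_translation():
    t = assemble_affine(np.eye(3), [10, 20, 30])
    p = camera_to_base(Point3D(1, 2, 3, "camera"), t)
    assert (p.x, p.y, p.z) == (11, 22, 33)


def test_camera_to_base_frame_tag_enforced():
    with pytest.raises(ValueError):
        camera_to_base(Point3D(0, 0, 1, "base"), np.eye(4))


def test_transform_roundtrip_through_inverse():
    calib = HandEyeCalibration((0.7, -0.3, 0.2, 0.4), (0.2, 0.3, 1.0), "m")
    t = calib.transform_mm
    p = Point3D(120.0, -40.0, 800.0, "camera")
    out = camera_to_base(p, t)
    back = np.linalg.inv(t) @ out.homogeneous
    np.testing.assert_allclose(back[:3], p.xyz, atol=1e-12)


def test_depth_fallback_median_patch():
    depth = np.full((10, 10), 500.0)
    depth[5, 5] = 0.0
    assert depth_at(depth, 5, 5) == 500.0
    assert depth_at(depth, 5, 5, fallback_patch=None) == 0.0
    with pytest.raises(ValueError):
        depth_at(depth, 50, 5)


def test_locate_fruit_empty_detections():
    k = CameraIntrinsics(500, 500, 320, 240)
    calib = HandEyeCalibration((1, 0, 0, 0), (0, 0, 0), "m")
    pts, fails = locate_fruit([], np.ones((480, 640)), k, calib)
    assert pts == [] and fails == []


def test_locate_fruit_misaligned_shapes_rejected():
    k = CameraIntrinsics(500, 500, 320, 240)
    calib = HandEyeCalibration((1, 0, 0, 0), (0, 0, 0), "m")
    with pytest.raises(ValueError):
        locate_fruit([], np.ones((100, 100)), k, calib, rgb_shape=(480, 640, 3))


def test_two_fruit_depth_ordering():
    k = CameraIntrinsics(500, 500, 320, 240)
    calib = HandEyeCalibration((1, 0, 0, 0), (0, 0, 0), "mm")
    cam = SimulatedRGBDCamera(k, calib)
    near = np.array([50.0, 0.0, 400.0])
    far = np.array([-80.0, 10.0, 1200.0])
    depth, dets = cam.render([near, far], radius_px=4)
    pts, fails = locate_fruit(dets, depth, k, calib)
    assert not fails
    zs = sorted(p.z for p in pts)
    assert zs[0] == pytest.approx(1200.0, abs=1e-9) or zs[1] == pytest.approx(1200.0, abs=1e-9)
    assert min(zs) == pytest.approx(400.0, abs=1e-9)


def test_full_pipeline_parameter_recovery_100_random_pairs():
    """Simulated camera, random pose and fruit: recovered base-frame points
    match the simulated ones to < 1e-6 of the scene scale with exact depth."""
    rng = np.random.default_rng(42)
    k = CameraIntrinsics(615.0, 615.0, 320.0, 240.0)
    worst = 0.0
    for trial in range(100):
        q = rng.standard_normal(4)
        calib = HandEyeCalibration(tuple(q / np.linalg.norm(q)),
                                   tuple(rng.uniform(-1, 1, 3)), "m")
        cam = SimulatedRGBDCamera(k, calib)
        pt = cam.random_visible_points(1, rng)[0]
        u, v, z = cam.project(pt)
        rec = camera_to_base(deproject(u, v, z, k), calib.transform_mm)
        worst = max(worst, np.abs(rec.xyz - pt).max())
    scene_scale = 1500.0  # mm working depth
    assert worst < 1e-6 * scene_scale


def test_noise_propagation_matches_folded_normal():
    """Gaussian depth noise sigma: mean |error| along the optical axis must
    approach sigma*sqrt(2/pi) (folded-normal mean)."""
    rng = np.random.default_rng(7)
    k = CameraIntrinsics(615.0, 615.0, 320.0, 240.0)
    calib = HandEyeCalibration((1, 0, 0, 0), (0, 0, 0), "mm")
    sigma = 5.0
    errors = []
    for _ in range(4000):
        u, v = rng.uniform(100, 540), rng.uniform(100, 380)
        z = rng.uniform(400, 1200)
        true = deproject(u, v, z, k).xyz
        noisy = deproject(u, v, z + rng.normal(0, sigma), k).xyz
        errors.append(noisy - true)
    errors = np.array(errors)
    expected = sigma * np.sqrt(2 / np.pi)
    assert np.abs(errors[:, 2]).mean() == pytest.approx(expected, rel=0.1)
    # lateral errors scale like sigma * |offset|/f << axial error
    assert np.abs(errors[:, 0]).mean() < expected


def test_calibration_yaml_roundtrip():
    calib = HandEyeCalibration((0.8, 0.1, 0.2, -0.3), (0.4, 0.5, 0.6), "m")
    back = HandEyeCalibration.from_yaml(calib.to_yaml())
    np.testing.assert_allclose(back.quaternion, calib.quaternion)
    assert back.unit == "m"
    k = CameraIntrinsics(600, 610, 320, 240)
    assert CameraIntrinsics.from_yaml(k.to_yaml()) == k
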