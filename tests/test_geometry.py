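"""Rigid registration, calibration arithmetic and tracking-noise contracts."""

import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from drillnav.geometry import (
    SHAFT_LENGTH_MM,
    CalibrationRecord,
    DegenerateGeometryError,
    FiducialSet,
    InvalidCalibrationError,
    NoiseModel,
    RigidTransform,
    TrackedPose,
    apply_calibration,
    calibrate_tip,
    minimal_rotation_between,
    perturb_pose,
    perturb_trajectory,
    register_fiducials,
    Trajectory,
)


def brute_force_rigid_fit(src, dst):
    """Independent oracle: least-squares over a rotation-vector chart."""

    def residuals(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        return ((src @ R.T + x[3:]) - dst).ravel()

    best = None
    for rv0 in ([0, 0, 0], [0.5, 0, 0], [0, 1.5, 0], [0, 0, -2.0]):
        x0 = np.concatenate([rv0, dst.mean(axis=0) - src.mean(axis=0)])
        fit = least_squares(residuals, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or fit.cost < best.cost:
            best = fit
    rms = np.sqrt(2.0 * best.cost / len(src))
    return rms


class TestRegisterFiducials:
    def test_identity_on_identical_points(self):
        pts = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]])
        T, fre = register_fiducials(FiducialSet(pts, pts.copy()))
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(T.translation, 0, atol=1e-12)
        assert fre == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_known_transform(self, seed):
        rng = np.random.default_rng(seed)
        phys = rng.uniform(-60, 60, (4, 3))
        R = Rotation.from_rotvec(rng.uniform(-1, 1, 3)).as_matrix()
        t = rng.uniform(-30, 30, 3)
        img = phys @ R.T + t
        T, fre = register_fiducials(FiducialSet(img, phys))
        assert np.abs(T.rotation - R).max() < 1e-9
        assert np.abs(T.translation - t).max() < 1e-9
        assert fre < 1e-9
        assert np.abs(T.apply(phys) - img).max() < 1e-9

    def test_noisy_fit_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        phys = np.array([[0.0, 0, 0], [40, 0, 0], [0, 40, 0], [10, 10, 30]])
        R = Rotation.from_rotvec([0.2, -0.4, 0.1]).as_matrix()
        img = phys @ R.T + [5.0, -2.0, 7.0] + rng.normal(0, 0.3, (4, 3))
        _, fre = register_fiducials(FiducialSet(img, phys))
        assert 0.0 < fre < 3 * 0.3
        assert fre == pytest.approx(brute_force_rigid_fit(phys, img), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_fre_invariant_under_joint_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        phys = rng.uniform(-40, 40, (6, 3))
        img = phys + rng.normal(0, 0.5, (6, 3))
        _, fre0 = register_fiducials(FiducialSet(img, phys))
        Q = Rotation.from_rotvec(rng.uniform(-2, 2, 3)).as_matrix()
        s = rng.uniform(-50, 50, 3)
        _, fre1 = register_fiducials(FiducialSet(img @ Q.T + s, phys @ Q.T + s))
        assert fre1 == pytest.approx(fre0, abs=1e-9)

    def test_degenerate_configurations_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            FiducialSet(np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]], np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            register_fiducials(FiducialSet(line, line.copy()))


class TestCalibration:
    @pytest.mark.parametrize("depth,travel,offset", [(5.0, 5.0, 0.0), (5.0, 7.0, 2.0)])
    def test_offset_is_travel_minus_depth(self, depth, travel, offset):
        rec = calibrate_tip(depth, travel)
        assert rec.tip_offset == pytest.approx(offset)

    def test_invalid_depth_rejected(self):
        with pytest.raises(InvalidCalibrationError):
            calibrate_tip(0.0, 2.0)

    def test_corrected_pose_has_fixed_shaft_length(self, pose_factory):
        pose = pose_factory([3.0, -2.0, 7.0], shaft=[1.0, 2.0, 2.0])
        rec = calibrate_tip(5.0, 7.0)
        out = apply_calibration(rec, pose)
        u = pose.shaft_direction
        assert np.allclose(out.tip, pose.tip + 2.0 * u)
        assert np.linalg.norm(out.hind - out.tip) == pytest.approx(SHAFT_LENGTH_MM, abs=1e-6)

    def test_zero_offset_idempotent(self, pose_factory):
        pose = pose_factory([1.0, 2.0, 3.0])
        rec = CalibrationRecord(divot_depth=4.0, tip_travel=4.0)
        out = apply_calibration(rec, apply_calibration(rec, pose))
        assert np.allclose(out.tip, pose.tip)
        assert np.allclose(out.hind, pose.hind)


class TestPerturbPose:
    def test_zero_sigma_is_identity(self, pose_factory):
        pose = pose_factory([1.0, 2.0, 3.0])
        out = perturb_pose(pose, NoiseModel(0.0, 0.0, seed=3))
        assert np.array_equal(out.tip, pose.tip)
        assert np.allclose(out.hind, pose.hind)

    def test_seed_reproducibility(self, pose_factory):
        pose = pose_factory([5.0, 5.0, 5.0])
        nm = NoiseModel(1.0, 1.0, seed=11)
        a, b = perturb_pose(pose, nm), perturb_pose(pose, nm)
        assert np.array_equal(a.tip, b.tip) and np.array_equal(a.hind, b.hind)

    def test_mean_displacement_matches_maxwell(self, pose_factory):
        # |N(0, sigma^2 I_3)| has mean sigma * 2 sqrt(2/pi)
        nm = NoiseModel(1.0, 0.0, seed=7)
        rng = nm.rng()
        pose = pose_factory([0.0, 0.0, 0.0])
        from drillnav.geometry import _perturb

        disp = [np.linalg.norm(_perturb(pose, nm, rng).tip - pose.tip) for _ in range(10_000)]
        expected = 2.0 * np.sqrt(2.0 / np.pi)
        assert np.mean(disp) == pytest.approx(expected, rel=0.02)

    def test_shaft_renormalised_after_noise(self, pose_factory):
        pose = pose_factory([0.0, 0.0, 0.0])
        traj = perturb_trajectory(Trajectory((pose,) * 5), NoiseModel(2.0, 2.0, seed=1))
        for p in traj:
            assert np.linalg.norm(p.hind - p.tip) == pytest.approx(SHAFT_LENGTH_MM, abs=1e-9)


class TestRigidTransform:
    def test_compose_and_inverse_close_under_type(self):
        rng = np.random.default_rng(0)
        A = RigidTransform(Rotation.from_rotvec(rng.uniform(-1, 1, 3)).as_matrix(), rng.uniform(-5, 5, 3))
        B = RigidTransform(Rotation.from_rotvec(rng.uniform(-1, 1, 3)).as_matrix(), rng.uniform(-5, 5, 3))
        p = rng.uniform(-10, 10, (7, 3))
        assert np.allclose(A.compose(B).apply(p), A.apply(B.apply(p)), atol=1e-12)
        assert np.allclose(A.compose(A.inverse()).apply(p), p, atol=1e-9)

    def test_improper_rotation_rejected(self):
        M = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(M, np.zeros(3))

    @pytest.mark.parametrize("a,b", [
        ([0, 0, 1], [0, 0, 1]),
        ([0, 0, 1], [1, 0, 0]),
        ([0, 0, 1], [0, 0, -1]),
        ([1, 2, 3], [-2, 0.5, 1]),
    ])
    def test_minimal_rotation_maps_a_to_b(self, a, b):
        R = minimal_rotation_between(a, b)
        a = np.asarray(a, float) / np.linalg.norm(a)
        b = np.asarray(b, float) / np.linalg.norm(b)
        assert np.allclose(R @ a, b, atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
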