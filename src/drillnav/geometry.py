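"""Rigid coordinate geometry for navigated drilling.

All coordinates are world millimetres unless stated otherwise. The tool
axis convention is that a tracked instrument is described by its tip and a
hind point fixed ``SHAFT_LENGTH_MM`` (100 mm) up the shaft from the tip;
every operation that moves a pose re-establishes that length exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SHAFT_LENGTH_MM",
    "RigidTransform",
    "FiducialSet",
    "TrackedPose",
    "Trajectory",
    "CalibrationRecord",
    "NoiseModel",
    "register_fiducials",
    "calibrate_tip",
    "apply_calibration",
    "perturb_pose",
    "perturb_trajectory",
]

#: Fixed tip-to-hind shaft length of a calibrated instrument (mm).
SHAFT_LENGTH_MM = 100.0

_ORTHO_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when a point configuration cannot support the requested fit."""


class InvalidCalibrationError(ValueError):
    """Raised for physically meaningless calibration inputs."""


def _as_vec3(x, name: str = "vector") -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    return v


def _as_points(x, name: str = "points") -> np.ndarray:
    p = np.asarray(x, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError(f"{name} must be an (N, 3) array, got shape {p.shape}")
    return p


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R x + t`` of 3-space.

    The rotation must be orthonormal with determinant +1 (checked to 1e-9).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = _as_vec3(self.translation, "translation")
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return cls(m[:3, :3], m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to a 3-vector or an (N, 3) array of points."""
        p = np.asarray(points, dtype=float)
        if p.ndim == 1:
            return self.rotation @ p + self.translation
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


@dataclass(frozen=True)
class FiducialSet:
    """Index-paired fiducial coordinates in image space and tracker space."""

    image_points: np.ndarray
    physical_points: np.ndarray

    def __post_init__(self) -> None:
        img = _as_points(self.image_points, "image_points")
        phys = _as_points(self.physical_points, "physical_points")
        if len(img) != len(phys):
            raise ValueError("image and physical point lists differ in length")
        if len(img) < 3:
            raise DegenerateGeometryError("at least 3 fiducial pairs are required")
        d = np.linalg.norm(img[:, None, :] - img[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-9:
            raise ValueError("coincident image fiducials")
        object.__setattr__(self, "image_points", img)
        object.__setattr__(self, "physical_points", phys)

    def __len__(self) -> int:
        return len(self.image_points)


@dataclass(frozen=True)
class TrackedPose:
    """One tracking sample: timestamp plus tip and hind points (image mm)."""

    t: float
    tip: np.ndarray
    hind: np.ndarray

    def __post_init__(self) -> None:
        tip = _as_vec3(self.tip, "tip")
        hind = _as_vec3(self.hind, "hind")
        if np.linalg.norm(hind - tip) <= 0:
            raise ValueError("tip and hind coincide")
        object.__setattr__(self, "tip", tip)
        object.__setattr__(self, "hind", hind)

    @property
    def shaft_direction(self) -> np.ndarray:
        """Unit vector from tip toward hind."""
        v = self.hind - self.tip
        return v / np.linalg.norm(v)

    def with_shaft_length(self, length: float = SHAFT_LENGTH_MM) -> "TrackedPose":
        return replace(self, hind=self.tip + length * self.shaft_direction)


@dataclass(frozen=True)
class Trajectory:
    """An ordered, non-decreasing-in-time sequence of tracked poses."""

    poses: tuple[TrackedPose, ...]

    def __post_init__(self) -> None:
        poses = tuple(self.poses)
        times = [p.t for p in poses]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("pose timestamps must be non-decreasing")
        object.__setattr__(self, "poses", poses)

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    def tips(self) -> np.ndarray:
        return np.array([p.tip for p in self.poses]).reshape(-1, 3)


@dataclass(frozen=True)
class CalibrationRecord:
    """Tip-length correction from the divot calibration procedure.

    ``tip_travel`` is the shaft-axis travel of the tracked tip between the
    in-divot and beside-divot placements; a bit too wide to reach the divot
    bottom travels further than the divot is deep, and the surplus
    ``tip_offset = tip_travel - divot_depth`` is applied to the modelled tip
    along the shaft (toward the hind).
    """

    divot_depth: float
    tip_travel: float

    @property
    def tip_offset(self) -> float:
        return self.tip_travel - self.divot_depth


@dataclass(frozen=True)
class NoiseModel:
    """Per-axis Gaussian position noise for simulated tracking (mm)."""

    sigma_tip: float = 0.8
    sigma_hind: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_tip < 0 or self.sigma_hind < 0:
            raise ValueError("noise sigmas must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def register_fiducials(fiducials: FiducialSet) -> tuple[RigidTransform, float]:
    """Least-squares rigid patient-to-image registration.

    Finds the proper rigid transform ``T`` minimising
    ``sum_i |T(physical_i) - image_i|^2`` (Kabsch/SVD solution) and returns
    it with the fiducial registration error, the RMS residual after
    alignment.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 pairs or a collinear physical configuration.
    """
    src = fiducials.physical_points
    dst = fiducials.image_points
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)

    s = np.linalg.svd(src_c, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("fiducials are collinear")

    H = src_c.T @ dst_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = dst.mean(axis=0) - R @ src.mean(axis=0)
    transform = RigidTransform(R, t)

    residuals = transform.apply(src) - dst
    fre = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return transform, fre


def calibrate_tip(divot_depth: float, tip_travel: float) -> CalibrationRecord:
    """Build the tip correction from the divot-depth calibration step."""
    if divot_depth <= 0:
        raise InvalidCalibrationError("divot depth must be positive")
    return CalibrationRecord(divot_depth=float(divot_depth), tip_travel=float(tip_travel))


def apply_calibration(record: CalibrationRecord, pose: TrackedPose) -> TrackedPose:
    """Shift the tip by the calibration offset along the shaft.

    The corrected hind is re-placed exactly ``SHAFT_LENGTH_MM`` from the
    corrected tip along the unchanged shaft direction.
    """
    u = pose.shaft_direction
    tip = pose.tip + record.tip_offset * u
    return TrackedPose(t=pose.t, tip=tip, hind=tip + SHAFT_LENGTH_MM * u)


def _perturb(pose: TrackedPose, noise: NoiseModel, rng: np.random.Generator) -> TrackedPose:
    tip = pose.tip + rng.normal(0.0, noise.sigma_tip, 3)
    hind = pose.hind + rng.normal(0.0, noise.sigma_hind, 3)
    return TrackedPose(t=pose.t, tip=tip, hind=hind).with_shaft_length()


def perturb_pose(pose: TrackedPose, noise: NoiseModel) -> TrackedPose:
    """Apply one seeded draw of per-axis Gaussian tracking noise to a pose.

    Deterministic: the same pose, sigmas and seed reproduce the same output.
    The shaft is renormalised to 100 mm after perturbation.
    """
    return _perturb(pose, noise, noise.rng())


def perturb_trajectory(traj: Trajectory, noise: NoiseModel) -> Trajectory:
    """Perturb every pose of a trajectory with one seeded noise stream."""
    rng = noise.rng()
    return Trajectory(tuple(_perturb(p, noise, rng) for p in traj))


def minimal_rotation_between(a, b) -> np.ndarray:
    """Rotation matrix taking unit vector *a* to unit vector *b* with no roll.

    The minimal (smallest-angle) rotation about ``a x b``; the antiparallel
    case uses a half-turn about any axis orthogonal to *a*.
    """
    a = _as_vec3(a) / np.linalg.norm(a)
    b = _as_vec3(b) / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: 180 degrees about an axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
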