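"""Synthetic phantoms, drill-bit clouds and scripted trajectories.

Everything the in-silico experiments consume is generated here, emulating
the two physical test objects of a navigated temporal-bone drilling study:

* a cylinder-and-ball accuracy phantom — 19 cylinders of varied height
  carrying hollow ball shells whose centres are the known targets, plus
  4 metal screw fiducials;
* drillable temporal-bone blocks with a straight facial-nerve canal
  (metal rod inside), a sigmoid-sinus blob, a tumour blob and 6 divot
  fiducials, at two CT geometries (anisotropic 0.18x0.18x1.0 mm and
  isotropic-protocol 0.34x0.34x0.4 mm voxels).

Intensities are HU-like and fixed: air -1000, silicone 100, ball shells
800, bone 1500, metal 3000, so segmentation windows are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import SHAFT_LENGTH_MM, FiducialSet, TrackedPose, Trajectory
from .proximity import DEFAULT_MANTLE_MM, CriticalStructure

__all__ = [
    "HU_AIR",
    "HU_SILICONE",
    "HU_SHELL",
    "HU_BONE",
    "HU_METAL",
    "VoxelVolume",
    "DrillBitModel",
    "PhantomTruth",
    "make_cylinder_ball_phantom",
    "make_temporal_bone_phantom",
    "build_drill_bit",
    "make_trajectory",
    "plan_approach",
    "sample_sphere_surface",
    "sample_cylinder_surface",
    "sample_capsule_surface",
]

HU_AIR = -1000.0
HU_SILICONE = 100.0
HU_SHELL = 800.0
HU_BONE = 1500.0
HU_METAL = 3000.0

#: Update period of the pose stream (s).
POSE_PERIOD_S = 0.16

#: Surface-cloud sampling pitch for critical structures (mm).
STRUCTURE_PITCH_MM = 0.1


class ConfigurationError(ValueError):
    """Requested phantom geometry cannot be realised."""


@dataclass
class VoxelVolume:
    """A 3D scalar navigation image with a voxel-index-to-world-mm affine.

    The affine maps 0-based voxel indices to the world-mm coordinates of
    voxel centres. ``background`` is the intensity that erased (air)
    voxels take.
    """

    data: np.ndarray
    affine: np.ndarray
    background: float = HU_AIR

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("data must be a non-empty 3D grid")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-15:
            raise ValueError("affine is singular")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Continuous (unrounded) voxel indices of world-mm points."""
        world = np.asarray(world, dtype=float)
        inv = np.linalg.inv(self.affine)
        return world @ inv[:3, :3].T + inv[:3, 3]

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.affine.copy(), self.background)


@dataclass
class DrillBitModel:
    """Point-cloud model of a drill bit in a tool-local frame.

    Local convention: the tip is at the origin, the shaft axis is +z with
    the hind at ``(0, 0, 100)`` mm; the bit solid occupies z >= 0.
    """

    points: np.ndarray
    tip: np.ndarray
    hind: np.ndarray
    diameter: float
    shape: str
    sampling_pitch: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.tip = np.asarray(self.tip, dtype=float)
        self.hind = np.asarray(self.hind, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) == 0:
            raise ValueError("points must be a non-empty (N, 3) array")


@dataclass
class PhantomTruth:
    """A synthetic phantom with its exhaustive ground truth."""

    volume: VoxelVolume
    target_points: np.ndarray
    fiducials: FiducialSet
    structures: list[CriticalStructure] = field(default_factory=list)
    tumor_mask: np.ndarray | None = None
    structure_masks: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# analytic surface sampling (<= 0.1 mm pitch, exact to the generating shape)

def sample_sphere_surface(center, radius: float, pitch: float = STRUCTURE_PITCH_MM) -> np.ndarray:
    """Near-uniform Fibonacci sampling of a sphere surface at <= pitch mm."""
    center = np.asarray(center, dtype=float)
    n = max(int(np.ceil(4.0 * np.pi * radius**2 / (0.6 * pitch) ** 2)), 16)
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r_xy = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pts = np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])
    return center + radius * pts


def _axis_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w = direction / np.linalg.norm(direction)
    a = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(w, a)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v, w


def sample_cylinder_surface(p0, p1, radius: float, pitch: float = STRUCTURE_PITCH_MM) -> np.ndarray:
    """Regular grid on the lateral surface of a finite cylinder."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    u, v, w = _axis_frame(p1 - p0)
    length = float(np.linalg.norm(p1 - p0))
    n_th = max(int(np.ceil(2.0 * np.pi * radius / pitch)), 6)
    n_z = max(int(np.ceil(length / pitch)) + 1, 2)
    th = np.linspace(0.0, 2.0 * np.pi, n_th, endpoint=False)
    zz = np.linspace(0.0, length, n_z)
    ring = radius * (np.outer(np.cos(th), u) + np.outer(np.sin(th), v))
    pts = (p0 + zz[:, None, None] * w + ring[None, :, :]).reshape(-1, 3)
    return pts


def sample_capsule_surface(p0, p1, radius: float, pitch: float = STRUCTURE_PITCH_MM) -> np.ndarray:
    """Cylinder side plus hemispherical end caps."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    w = (p1 - p0) / np.linalg.norm(p1 - p0)
    side = sample_cylinder_surface(p0, p1, radius, pitch)
    cap0 = sample_sphere_surface(p0, radius, pitch)
    cap0 = cap0[(cap0 - p0) @ w <= 0]
    cap1 = sample_sphere_surface(p1, radius, pitch)
    cap1 = cap1[(cap1 - p1) @ w >= 0]
    return np.concatenate([side, cap0, cap1], axis=0)


# ---------------------------------------------------------------------------
# voxel painting helpers (axis-aligned diagonal affines, construction only)

def _diag_volume(shape, spacing, origin, fill: float) -> VoxelVolume:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = spacing
    affine[:3, 3] = origin
    data = np.full(shape, fill, dtype=np.float32)
    return VoxelVolume(data, affine, background=HU_AIR)


def _bbox(vol: VoxelVolume, lo_world, hi_world) -> tuple[slice, slice, slice] | None:
    spacing = np.diag(vol.affine[:3, :3])
    origin = vol.affine[:3, 3]
    lo = np.floor((np.asarray(lo_world) - origin) / spacing).astype(int)
    hi = np.ceil((np.asarray(hi_world) - origin) / spacing).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, vol.shape)
    if np.any(lo >= hi):
        return None
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _centers(vol: VoxelVolume, sl) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    spacing = np.diag(vol.affine[:3, :3])
    origin = vol.affine[:3, 3]
    ax = [origin[i] + spacing[i] * np.arange(sl[i].start, sl[i].stop) for i in range(3)]
    return np.meshgrid(*ax, indexing="ij")


def _paint_sphere(vol: VoxelVolume, center, radius, value, inner_radius=None,
                  mask_out: np.ndarray | None = None) -> None:
    center = np.asarray(center, dtype=float)
    sl = _bbox(vol, center - radius, center + radius)
    if sl is None:
        return
    X, Y, Z = _centers(vol, sl)
    d2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    sel = d2 <= radius**2
    if inner_radius is not None:
        sel &= d2 >= inner_radius**2
    vol.data[sl][sel] = value
    if mask_out is not None:
        mask_out[sl][sel] = True


def _paint_capsule(vol: VoxelVolume, p0, p1, radius, value,
                   mask_out: np.ndarray | None = None) -> None:
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    lo = np.minimum(p0, p1) - radius
    hi = np.maximum(p0, p1) + radius
    sl = _bbox(vol, lo, hi)
    if sl is None:
        return
    X, Y, Z = _centers(vol, sl)
    pts = np.stack([X, Y, Z], axis=-1)
    d = _dist_to_segment(pts.reshape(-1, 3), p0, p1).reshape(X.shape)
    sel = d <= radius
    vol.data[sl][sel] = value
    if mask_out is not None:
        mask_out[sl][sel] = True


def _dist_to_segment(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    v = p1 - p0
    L2 = float(v @ v)
    if L2 == 0.0:
        return np.linalg.norm(points - p0, axis=1)
    s = np.clip((points - p0) @ v / L2, 0.0, 1.0)
    proj = p0 + s[:, None] * v
    return np.linalg.norm(points - proj, axis=1)


# ---------------------------------------------------------------------------
# phantoms

def make_cylinder_ball_phantom(
    n_cylinders: int = 19,
    spacing: float = 18.0,
    noise_texture: float = 10.0,
    seed: int = 0,
    shape: tuple[int, int, int] | None = None,
) -> PhantomTruth:
    """Build the cylinder-and-ball drill-tracking accuracy phantom.

    19 bone cylinders of per-seed varied height stand on a base slab; a
    hollow ball shell (distinct intensity) is centred on each cylinder's
    top point, which is the known target. Four metal screws near the base
    corners serve as fiducials. Voxels are 0.48 x 0.48 x 1.0 mm.

    ``spacing`` is the centre-to-centre cylinder pitch, ``noise_texture``
    the s.d. of additive Gaussian intensity noise. Deterministic per seed.
    """
    if n_cylinders < 1:
        raise ConfigurationError("need at least one cylinder")
    rng = np.random.default_rng(seed)
    vox = (0.48, 0.48, 1.0)
    cols = int(np.ceil(np.sqrt(n_cylinders)))
    rows = int(np.ceil(n_cylinders / cols))
    margin = 10.0
    ball_r, ball_inner = 6.0, 4.5
    base_top = 5.0
    heights = rng.uniform(25.0, 55.0, size=n_cylinders)

    extent = np.array([
        cols * spacing + 2 * margin,
        rows * spacing + 2 * margin,
        base_top + heights.max() + ball_r + 6.0,
    ])
    need = tuple(int(np.ceil(extent[i] / vox[i])) for i in range(3))
    if shape is None:
        shape = need
    elif any(s < n for s, n in zip(shape, need)):
        raise ConfigurationError(f"layout needs grid >= {need}, got {shape}")

    origin = (-extent[0] / 2.0, -extent[1] / 2.0, 0.0)
    vol = _diag_volume(shape, vox, origin, HU_AIR)

    # base slab
    sl = _bbox(vol, (origin[0] + 2, origin[1] + 2, 0.0),
               (origin[0] + extent[0] - 2, origin[1] + extent[1] - 2, base_top))
    vol.data[sl] = HU_BONE

    targets = []
    for i in range(n_cylinders):
        cx = origin[0] + margin + (i % cols + 0.5) * spacing
        cy = origin[1] + margin + (i // cols + 0.5) * spacing
        top = base_top + heights[i]
        _paint_capsule(vol, (cx, cy, 0.0), (cx, cy, top), 2.5, HU_BONE)
        # hollow ball shell centred on the cylinder-top target point
        _paint_sphere(vol, (cx, cy, top), ball_r, HU_SHELL, inner_radius=ball_inner)
        targets.append((cx, cy, top))
    targets = np.array(targets)

    screw_xy = np.array([
        [origin[0] + 5.0, origin[1] + 5.0],
        [origin[0] + extent[0] - 5.0, origin[1] + 5.0],
        [origin[0] + 5.0, origin[1] + extent[1] - 5.0],
        [origin[0] + extent[0] - 5.0, origin[1] + extent[1] - 5.0],
    ])
    screws = np.column_stack([screw_xy, np.full(4, base_top - 2.0)])
    for p in screws:
        _paint_sphere(vol, p, 1.5, HU_METAL)

    if noise_texture > 0:
        vol.data += rng.normal(0.0, noise_texture, vol.shape).astype(np.float32)

    fid = FiducialSet(image_points=screws, physical_points=screws.copy())
    seed_offset = np.array([0.0, 0.0, 0.5 * (ball_r + ball_inner)])
    return PhantomTruth(
        volume=vol,
        target_points=targets,
        fiducials=fid,
        meta={
            "ball_outer_mm": ball_r,
            "ball_inner_mm": ball_inner,
            "shell_window": (HU_SHELL - 300.0, HU_SHELL + 300.0),
            "ball_seed_points": targets + seed_offset,
        },
    )


def make_temporal_bone_phantom(
    index_style: str = "isotropic",
    seed: int = 0,
    size_mm: tuple[float, float, float] = (40.0, 40.0, 32.0),
    mantle: float = DEFAULT_MANTLE_MM,
    noise_texture: float = 10.0,
) -> PhantomTruth:
    """Build a drillable temporal-bone block phantom.

    A bone block carries: a straight facial-nerve canal along y (air canal
    with a metal rod inside), a sigmoid-sinus capsule near the far face, a
    silicone tumour sphere, and 6 divot fiducials on the top face.
    Structure placement jitters by +-2 mm / +-5 degrees per seed, so each
    model differs slightly from the next. Voxels are 0.18 x 0.18 x 1.0 mm
    (``anisotropic``) or 0.34 x 0.34 x 0.4 mm (``isotropic``).
    """
    if index_style == "anisotropic":
        vox = (0.18, 0.18, 1.0)
    elif index_style == "isotropic":
        vox = (0.34, 0.34, 0.4)
    else:
        raise ConfigurationError(f"unknown index_style {index_style!r}")
    rng = np.random.default_rng(seed)
    sx, sy, sz = size_mm
    shape = tuple(int(np.ceil(size_mm[i] / vox[i])) for i in range(3))
    vol = _diag_volume(shape, vox, (0.0, 0.0, 0.0), HU_AIR)

    bone_lo = np.array([2.0, 2.0, 2.0])
    bone_hi = np.array([sx - 2.0, sy - 2.0, sz - 2.0])
    vol.data[_bbox(vol, bone_lo, bone_hi)] = HU_BONE
    bone_top = bone_hi[2]

    def jit(scale=2.0):
        return rng.uniform(-scale, scale)

    def tilt(base_dir, max_deg=5.0):
        d = np.asarray(base_dir, dtype=float)
        u, v, _ = _axis_frame(d)
        ang = np.deg2rad(rng.uniform(0.0, max_deg))
        phi = rng.uniform(0.0, 2.0 * np.pi)
        t = d / np.linalg.norm(d) + np.tan(ang) * (np.cos(phi) * u + np.sin(phi) * v)
        return t / np.linalg.norm(t)

    # facial-nerve canal: straight, roughly along y, mid-depth
    canal_r, rod_r = 1.5, 0.8
    c_mid = np.array([0.30 * sx + jit(), sy / 2.0, 0.30 * sz + jit(1.5)])
    c_dir = tilt([0.0, 1.0, 0.0])
    half = 0.40 * sy
    n0, n1 = c_mid - half * c_dir, c_mid + half * c_dir
    nerve_mask = np.zeros(shape, dtype=bool)
    _paint_capsule(vol, n0, n1, canal_r, HU_AIR, mask_out=nerve_mask)
    _paint_capsule(vol, n0, n1, rod_r, HU_METAL)

    # sigmoid sinus: silicone capsule near the far (high-x) face, along z
    sin_r = 2.5
    s_mid = np.array([0.82 * sx + jit(1.0), sy / 2.0 + jit(), sz / 2.0])
    s_dir = tilt([0.0, 0.0, 1.0])
    s_half = 0.28 * sz
    s0, s1 = s_mid - s_half * s_dir, s_mid + s_half * s_dir
    sinus_mask = np.zeros(shape, dtype=bool)
    _paint_capsule(vol, s0, s1, sin_r, HU_SILICONE, mask_out=sinus_mask)

    # tumour: silicone sphere deep in the block, clear of nerve and sinus
    tum_r = 5.0
    t_c = np.array([0.62 * sx + jit(1.0), sy / 2.0 + jit(1.0), 0.32 * sz + jit(1.0)])
    tumor_mask = np.zeros(shape, dtype=bool)
    _paint_sphere(vol, t_c, tum_r, HU_SILICONE, mask_out=tumor_mask)

    # six divot fiducials on the top face
    div = []
    for i in range(6):
        dx = 0.15 * sx + 0.14 * sx * i + rng.uniform(-1.0, 1.0)
        dy = (0.22 if i % 2 == 0 else 0.78) * sy + rng.uniform(-1.0, 1.0)
        p = np.array([dx, dy, bone_top])
        _paint_sphere(vol, p, 1.2, HU_AIR)
        div.append(p)
    divots = np.array(div)

    if noise_texture > 0:
        vol.data += rng.normal(0.0, noise_texture, vol.shape).astype(np.float32)

    structures = [
        CriticalStructure("facial_nerve",
                          sample_cylinder_surface(n0, n1, canal_r), mantle),
        CriticalStructure("sigmoid_sinus",
                          sample_capsule_surface(s0, s1, sin_r), mantle),
    ]
    fid = FiducialSet(image_points=divots, physical_points=divots.copy())
    return PhantomTruth(
        volume=vol,
        target_points=t_c.reshape(1, 3),
        fiducials=fid,
        structures=structures,
        tumor_mask=tumor_mask,
        structure_masks={"facial_nerve": nerve_mask, "sigmoid_sinus": sinus_mask},
        meta={
            "bone_top_z": bone_top,
            "tumor_center": t_c,
            "tumor_radius": tum_r,
            "nerve_axis": (n0, n1),
            "nerve_radius": canal_r,
            "sinus_axis": (s0, s1),
            "sinus_radius": sin_r,
            "index_style": index_style,
        },
    )


# ---------------------------------------------------------------------------
# drill bits and trajectories

def build_drill_bit(
    shape: str = "sphere",
    diameter: float = 4.0,
    sampling_pitch: float = 0.2,
    stub_length: float = 0.0,
) -> DrillBitModel:
    """Point-sample an analytic drill-bit solid at the given pitch.

    ``sphere`` fills a ball of the given diameter whose most distal point
    is the tip (local origin); ``match_head`` adds a cylindrical neck of
    0.75 x radius behind the spherical head. ``stub_length`` optionally
    appends a thin shaft stub behind the head. The cloud lies on a regular
    grid of pitch ``sampling_pitch``, which should be at least as fine as
    the target image's voxel spacing.
    """
    if diameter <= 0 or sampling_pitch <= 0:
        raise ConfigurationError("diameter and sampling_pitch must be positive")
    if shape not in ("sphere", "match_head"):
        raise ConfigurationError(f"unknown bit shape {shape!r}")
    r = diameter / 2.0
    head_top = 2.0 * r if shape == "sphere" else 2.2 * r
    z_top = head_top + max(stub_length, 0.0)
    nxy = int(np.ceil(r / sampling_pitch))
    nz = int(np.ceil(z_top / sampling_pitch))
    ax_xy = sampling_pitch * np.arange(-nxy, nxy + 1)
    ax_z = sampling_pitch * np.arange(0, nz + 1)
    X, Y, Z = np.meshgrid(ax_xy, ax_xy, ax_z, indexing="ij")
    rho2 = X**2 + Y**2
    head = rho2 + (Z - r) ** 2 <= r**2 + 1e-12
    if shape == "match_head":
        neck = (rho2 <= (0.75 * r) ** 2 + 1e-12) & (Z >= r) & (Z <= head_top)
        head |= neck
    if stub_length > 0:
        stub_r = min(1.0, 0.4 * r)
        head |= (rho2 <= stub_r**2 + 1e-12) & (Z >= head_top) & (Z <= z_top)
    pts = np.column_stack([X[head], Y[head], Z[head]])
    return DrillBitModel(
        points=pts,
        tip=np.zeros(3),
        hind=np.array([0.0, 0.0, SHAFT_LENGTH_MM]),
        diameter=diameter,
        shape=shape,
        sampling_pitch=sampling_pitch,
    )


def make_trajectory(
    waypoints,
    shaft_dir,
    period: float = POSE_PERIOD_S,
    speed: float = 2.0,
    times: Sequence[float] | None = None,
) -> Trajectory:
    """Sample a piecewise-linear tip path at the tracking period.

    Waypoint times default to constant-speed traversal at ``speed`` mm/s;
    pass ``times`` to pin them. The hind point sits 100 mm from the tip
    along ``shaft_dir`` for every pose; endpoints are inclusive.
    """
    wp = np.atleast_2d(np.asarray(waypoints, dtype=float))
    if wp.shape[1] != 3 or len(wp) < 1:
        raise ValueError("waypoints must be (N, 3) with N >= 1")
    u = np.asarray(shaft_dir, dtype=float)
    nrm = np.linalg.norm(u)
    if nrm <= 0:
        raise ValueError("shaft_dir must be non-zero")
    u = u / nrm
    if times is None:
        seg = np.linalg.norm(np.diff(wp, axis=0), axis=1)
        times = np.concatenate([[0.0], np.cumsum(seg / speed)])
    else:
        times = np.asarray(times, dtype=float)
        if len(times) != len(wp):
            raise ValueError("times must match waypoints")
    t_end = float(times[-1])
    n = int(np.floor(t_end / period + 0.5)) if t_end > 0 else 0
    ts = period * np.arange(n + 1)
    tips = np.column_stack([np.interp(ts, times, wp[:, k]) for k in range(3)])
    poses = tuple(
        TrackedPose(t=float(t), tip=tip, hind=tip + SHAFT_LENGTH_MM * u)
        for t, tip in zip(ts, tips)
    )
    return Trajectory(poses)


def plan_approach(
    truth: PhantomTruth,
    style: str = "safe",
    speed: float = 2.0,
    period: float = POSE_PERIOD_S,
    start_above_mm: float = 5.0,
) -> Trajectory:
    """Script a straight vertical approach into a temporal-bone phantom.

    ``safe`` descends over the tumour centre and stops at the tumour
    surface, staying well clear of the nerve and sinus; ``reckless`` aims
    straight through the facial-nerve canal. The shaft points up (+z),
    mimicking drilling downward from the exposed top face.
    """
    meta = truth.meta
    top = meta["bone_top_z"]
    if style == "safe":
        c = meta["tumor_center"]
        entry = np.array([c[0], c[1], top + start_above_mm])
        stop = np.array([c[0], c[1], c[2] + meta["tumor_radius"] - 1.0])
    elif style == "reckless":
        n0, n1 = meta["nerve_axis"]
        mid = 0.5 * (np.asarray(n0) + np.asarray(n1))
        entry = np.array([mid[0], mid[1], top + start_above_mm])
        stop = np.array([mid[0], mid[1], mid[2]])
    else:
        raise ValueError(f"unknown approach style {style!r}")
    return make_trajectory([entry, stop], shaft_dir=(0.0, 0.0, 1.0),
                           period=period, speed=speed)
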