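"""Continuous drill-tip-to-critical-structure distance emission.

The warning mechanism measures the Euclidean distance from the tracked
drill tip to the nearest point of each critical structure's surface cloud
at every pose, and raises an "entered" event when that distance first drops
below the structure's safety mantle (a fixed-thickness buffer shell around
the segmented surface, 3 mm by default). The event log stands in for the
interface's audiovisual warning channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import Trajectory

__all__ = [
    "DEFAULT_MANTLE_MM",
    "CriticalStructure",
    "WarningEvent",
    "build_structure_from_mask",
    "nearest_distance",
    "emit_warnings",
    "detect_structure_hits",
]

#: Default safety-mantle thickness (mm).
DEFAULT_MANTLE_MM = 3.0

#: Maximum surface-cloud sampling pitch (mm).
SURFACE_PITCH_MM = 0.1


@dataclass
class CriticalStructure:
    """A named anatomical no-go surface as a dense point cloud.

    ``surface_points`` is an (M, 3) world-mm cloud sampled from the
    structure surface at <= 0.1 mm pitch; ``mantle`` is the safety-mantle
    thickness in mm.
    """

    name: str
    surface_points: np.ndarray
    mantle: float = DEFAULT_MANTLE_MM
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.surface_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
            raise ValueError("surface_points must be a non-empty (M, 3) array")
        if self.mantle < 0:
            raise ValueError("mantle must be non-negative")
        self.surface_points = pts

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.surface_points)
        return self._tree


@dataclass(frozen=True)
class WarningEvent:
    """One proximity event: a mantle crossing or an in-mantle dwell sample."""

    t: float
    structure: str
    distance: float
    transition: str  # entered | exited | inside

    def __post_init__(self) -> None:
        if self.transition not in ("entered", "exited", "inside"):
            raise ValueError(f"unknown transition {self.transition!r}")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


def build_structure_from_mask(
    mask: np.ndarray,
    affine: np.ndarray,
    name: str,
    mantle: float = DEFAULT_MANTLE_MM,
    pitch: float = SURFACE_PITCH_MM,
) -> CriticalStructure:
    """Sample the exposed voxel faces of a binary mask into a surface cloud.

    Every face of a mask voxel whose 6-neighbour in that direction is
    outside the mask (or outside the grid) is covered with a regular grid
    of world-space points at spacing <= ``pitch`` mm, edges inclusive.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    affine = np.asarray(affine, dtype=float)

    clouds = []
    for axis in range(3):
        for sign in (-1, 1):
            exposed = mask & ~_shifted(mask, axis, -sign)
            idx = np.argwhere(exposed).astype(float)
            if len(idx) == 0:
                continue
            # face center sits half a voxel from the voxel center
            face_centers_idx = idx.copy()
            face_centers_idx[:, axis] += 0.5 * sign
            a1, a2 = [a for a in range(3) if a != axis]
            offs = _face_offsets(affine, a1, a2, pitch)
            pts_idx = face_centers_idx[:, None, :] + offs[None, :, :]
            clouds.append(pts_idx.reshape(-1, 3))
    idx_pts = np.concatenate(clouds, axis=0)
    world = idx_pts @ affine[:3, :3].T + affine[:3, 3]
    return CriticalStructure(name=name, surface_points=world, mantle=mantle)


def _shifted(mask: np.ndarray, axis: int, sign: int) -> np.ndarray:
    """Mask shifted one voxel along *axis*; off-grid treated as outside."""
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if sign > 0:
        src[axis] = slice(None, -1)
        dst[axis] = slice(1, None)
    else:
        src[axis] = slice(1, None)
        dst[axis] = slice(None, -1)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _face_offsets(affine: np.ndarray, a1: int, a2: int, pitch: float) -> np.ndarray:
    """In-plane index-space offsets covering one voxel face at <= pitch mm."""
    s1 = float(np.linalg.norm(affine[:3, a1]))
    s2 = float(np.linalg.norm(affine[:3, a2]))
    n1 = max(int(np.ceil(s1 / pitch)), 1) + 1
    n2 = max(int(np.ceil(s2 / pitch)), 1) + 1
    u = np.linspace(-0.5, 0.5, n1)
    v = np.linspace(-0.5, 0.5, n2)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    offs = np.zeros((uu.size, 3))
    offs[:, a1] = uu.ravel()
    offs[:, a2] = vv.ravel()
    return offs


def nearest_distance(tip, structure: CriticalStructure) -> float:
    """Exact minimum Euclidean distance from *tip* to the surface cloud."""
    tip = np.asarray(tip, dtype=float)
    d, _ = structure.tree.query(tip)
    return float(d)


def emit_warnings(
    traj: Trajectory,
    structures: Sequence[CriticalStructure],
    record_inside: bool = True,
) -> tuple[pd.DataFrame, list[WarningEvent]]:
    """Stream per-pose distances and mantle-crossing events.

    An ``entered`` event fires on a strict crossing from >= mantle to
    < mantle, ``exited`` on the reverse; while the tip dwells inside the
    mantle an ``inside`` event is emitted per pose (the continuous warning
    re-emission), suppressible with ``record_inside=False``.
    """
    rows = []
    events: list[WarningEvent] = []
    inside = {s.name: False for s in structures}
    for pose in traj:
        for s in structures:
            d = nearest_distance(pose.tip, s)
            rows.append({"t_s": pose.t, "structure": s.name, "distance_mm": d,
                         "inside_mantle": d < s.mantle})
            if not inside[s.name] and d < s.mantle:
                events.append(WarningEvent(pose.t, s.name, d, "entered"))
                inside[s.name] = True
            elif inside[s.name] and d >= s.mantle:
                events.append(WarningEvent(pose.t, s.name, d, "exited"))
                inside[s.name] = False
            elif inside[s.name] and record_inside:
                events.append(WarningEvent(pose.t, s.name, d, "inside"))
    return pd.DataFrame(rows), events


def detect_structure_hits(cavity_mask: np.ndarray, structure_masks: dict[str, np.ndarray]) -> pd.DataFrame:
    """Count cavity voxels intersecting each structure mask.

    The in-silico stand-in for post-operative visual damage assessment: a
    structure is *hit* when at least one erased voxel lies inside it.
    """
    cavity_mask = getattr(cavity_mask, "mask", cavity_mask)
    cav = np.asarray(cavity_mask, dtype=bool)
    rows = []
    for name, m in structure_masks.items():
        m = np.asarray(m, dtype=bool)
        if m.shape != cav.shape:
            raise ValueError(f"structure mask {name!r} shape {m.shape} != cavity {cav.shape}")
        n = int(np.count_nonzero(cav & m))
        rows.append({"structure": name, "n_voxels": n, "hit": n > 0})
    return pd.DataFrame(rows)
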