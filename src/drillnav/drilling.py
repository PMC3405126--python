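"""Virtual drilling by voxel erasure.

At every tracked pose the drill-bit point cloud is rigidly posed in world
space, each point is mapped through the inverse image affine and rounded to
its nearest voxel, and those voxels are set to the background (air)
intensity. Folding this over a pose stream accumulates the virtual drill
cavity. The cavity is tracked as an explicit binary mask alongside the
intensity erasure, so downstream analysis never has to re-infer it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SHAFT_LENGTH_MM, TrackedPose, Trajectory, minimal_rotation_between
from .phantoms import DrillBitModel, VoxelVolume

__all__ = ["CavityMask", "pose_transform", "erase_at_pose", "drill_trajectory"]

log = logging.getLogger(__name__)


@dataclass
class CavityMask:
    """Binary record of erased voxels, aligned to its parent volume."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("cavity mask must be 3D")

    @classmethod
    def empty_like(cls, volume: VoxelVolume) -> "CavityMask":
        return cls(np.zeros(volume.shape, dtype=bool))

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))


def pose_transform(bit: DrillBitModel, pose: TrackedPose) -> np.ndarray:
    """Rigidly place the bit cloud at a tracked pose (world mm).

    Maps the bit-local tip onto ``pose.tip`` and the local shaft axis onto
    the pose's shaft direction using the minimal (roll-free) rotation; the
    axial roll is physically free for a spinning bit and this rule fixes it
    deterministically.
    """
    u_local = bit.hind - bit.tip
    n_local = np.linalg.norm(u_local)
    if n_local <= 0:
        raise ValueError("bit has a degenerate shaft")
    R = minimal_rotation_between(u_local / n_local, pose.shaft_direction)
    return (bit.points - bit.tip) @ R.T + pose.tip


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round halves away from zero (fixed tie rule, unlike banker's)."""
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def erase_at_pose(
    volume: VoxelVolume,
    bit: DrillBitModel,
    pose: TrackedPose,
    cavity: CavityMask | None = None,
    in_place: bool = False,
) -> tuple[VoxelVolume, CavityMask, int]:
    """Erase the bit-shaped voxel set at one pose.

    Each posed cloud point is nearest-neighbour interpolated to a voxel;
    in-bounds voxels take the background intensity and join the cavity
    mask. Out-of-bounds points are skipped silently (normal during the
    approach). Re-erasing already-erased voxels reports zero new voxels.
    By default the input volume is left untouched and a copy is returned;
    ``in_place=True`` mutates it.
    """
    if bit.sampling_pitch > volume.spacing.min() + 1e-12:
        log.warning(
            "bit cloud pitch %.3g mm is coarser than the finest voxel spacing %.3g mm; "
            "erasures may leave gaps", bit.sampling_pitch, volume.spacing.min(),
        )
    if not in_place:
        volume = volume.copy()
    if cavity is None:
        cavity = CavityMask.empty_like(volume)
    n_new = _erase(volume, cavity.mask, pose_transform(bit, pose))
    return volume, cavity, n_new


def _erase(volume: VoxelVolume, mask: np.ndarray, world_points: np.ndarray) -> int:
    idx = _round_half_away(volume.world_to_index(world_points)).astype(np.int64)
    shp = volume.shape
    ok = np.all((idx >= 0) & (idx < np.asarray(shp)), axis=1)
    if not ok.any():
        return 0
    i, j, k = idx[ok].T
    new = ~mask[i, j, k]
    if not new.any():
        return 0
    i, j, k = i[new], j[new], k[new]
    mask[i, j, k] = True
    volume.data[i, j, k] = volume.background
    # duplicate cloud points land on the same voxel; count distinct ones
    flat = (i * shp[1] + j) * shp[2] + k
    return int(np.unique(flat).size)


def drill_trajectory(
    volume: VoxelVolume,
    bit: DrillBitModel,
    traj: Trajectory,
    interpolate: bool = False,
    in_place: bool = False,
) -> tuple[VoxelVolume, CavityMask, pd.DataFrame]:
    """Fold voxel erasure over an ordered pose stream.

    With ``interpolate`` off (the faithful mode) erasure happens only at
    the received samples, so fast hand motion leaves scallops; with it on,
    intermediate poses are inserted so successive tips differ by at most
    half the finest voxel spacing, yielding a gap-free swept cavity.
    Returns the drilled volume, the cumulative cavity, and a per-pose log
    with columns (t_s, n_new_voxels, cumulative_voxels).
    """
    if not in_place:
        volume = volume.copy()
    cavity = CavityMask.empty_like(volume)
    rows = []
    cum = 0
    poses = list(traj)
    step_max = 0.5 * float(volume.spacing.min())
    prev: TrackedPose | None = None
    for pose in poses:
        sub = [pose]
        if interpolate and prev is not None:
            sub = _interpolated(prev, pose, step_max) + [pose]
        n_pose = 0
        for p in sub:
            _, _, n = erase_at_pose(volume, bit, p, cavity, in_place=True)
            n_pose += n
        cum += n_pose
        rows.append({"t_s": pose.t, "n_new_voxels": n_pose, "cumulative_voxels": cum})
        prev = pose
    log_df = pd.DataFrame(rows, columns=["t_s", "n_new_voxels", "cumulative_voxels"])
    return volume, cavity, log_df


def _interpolated(a: TrackedPose, b: TrackedPose, step_max: float) -> list[TrackedPose]:
    d = float(np.linalg.norm(b.tip - a.tip))
    if d <= step_max:
        return []
    n = int(np.ceil(d / step_max))
    out = []
    for s in np.arange(1, n) / n:
        tip = (1 - s) * a.tip + s * b.tip
        hind = (1 - s) * a.hind + s * b.hind
        out.append(TrackedPose(t=(1 - s) * a.t + s * b.t, tip=tip, hind=hind).with_shaft_length())
    return out
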