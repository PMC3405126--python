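"""File interchange: NIfTI volumes, CSV pose logs, JSON transforms/truth.

Volumes travel as NIfTI-1 (the background intensity rides in the header
``descrip`` field); pose logs are CSV with the columns
``t_s, tip_x_mm, tip_y_mm, tip_z_mm, hind_x_mm, hind_y_mm, hind_z_mm``;
rigid transforms are 4x4 row-major JSON; structure clouds go to ASCII PLY.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import RigidTransform, TrackedPose, Trajectory
from .phantoms import PhantomTruth, VoxelVolume
from .proximity import CriticalStructure

__all__ = [
    "save_volume",
    "load_volume",
    "save_pose_log",
    "load_pose_log",
    "save_transform",
    "load_transform",
    "save_point_cloud_ply",
    "load_point_cloud_ply",
    "save_structures",
    "load_structures",
]

POSE_COLUMNS = ["t_s", "tip_x_mm", "tip_y_mm", "tip_z_mm",
                "hind_x_mm", "hind_y_mm", "hind_z_mm"]


def save_volume(volume: VoxelVolume, path) -> str:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine)
    img.header["descrip"] = f"background={volume.background:g}".encode()
    nib.save(img, str(path))
    return str(path)


def load_volume(path) -> VoxelVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    descrip = bytes(img.header["descrip"].tobytes()).decode(errors="ignore")
    m = re.search(r"background=([-+0-9.eE]+)", descrip)
    background = float(m.group(1)) if m else float(data.min())
    return VoxelVolume(data=data, affine=np.asarray(img.affine), background=background)


def save_pose_log(traj: Trajectory, path) -> str:
    rows = [
        [p.t, *p.tip, *p.hind]
        for p in traj
    ]
    pd.DataFrame(rows, columns=POSE_COLUMNS).to_csv(path, index=False)
    return str(path)


def load_pose_log(path) -> Trajectory:
    df = pd.read_csv(path)
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pose log misses columns {missing}")
    poses = tuple(
        TrackedPose(
            t=float(r.t_s),
            tip=np.array([r.tip_x_mm, r.tip_y_mm, r.tip_z_mm]),
            hind=np.array([r.hind_x_mm, r.hind_y_mm, r.hind_z_mm]),
        )
        for r in df.itertuples()
    )
    return Trajectory(poses)


def save_transform(transform: RigidTransform, path) -> str:
    with open(path, "w") as f:
        json.dump({"matrix": transform.as_matrix().tolist()}, f, indent=2)
    return str(path)


def load_transform(path) -> RigidTransform:
    with open(path) as f:
        payload = json.load(f)
    return RigidTransform.from_matrix(np.array(payload["matrix"], dtype=float))


def save_point_cloud_ply(points: np.ndarray, path, comment: str = "") -> str:
    points = np.asarray(points, dtype=float)
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\n")
        if comment:
            f.write(f"comment {comment}\n")
        f.write(f"element vertex {len(points)}\n")
        f.write("property float x\nproperty float y\nproperty float z\n")
        f.write("end_header\n")
        for p in points:
            f.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
    return str(path)


def load_point_cloud_ply(path) -> np.ndarray:
    with open(path) as f:
        lines = f.read().splitlines()
    n = 0
    for i, line in enumerate(lines):
        if line.startswith("element vertex"):
            n = int(line.split()[-1])
        if line.strip() == "end_header":
            start = i + 1
            break
    else:
        raise ValueError("not an ASCII PLY file")
    pts = [tuple(map(float, l.split()[:3])) for l in lines[start:start + n]]
    return np.array(pts, dtype=float)


def save_structures(structures: list[CriticalStructure], directory) -> str:
    """Write a structure bundle: index JSON plus one PLY cloud per structure."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = []
    for s in structures:
        ply = directory / f"{s.name}.ply"
        save_point_cloud_ply(s.surface_points, ply, comment=f"structure {s.name}")
        index.append({"name": s.name, "mantle_mm": s.mantle, "cloud": ply.name})
    with open(directory / "structures.json", "w") as f:
        json.dump(index, f, indent=2)
    return str(directory / "structures.json")


def load_structures(index_path) -> list[CriticalStructure]:
    index_path = Path(index_path)
    with open(index_path) as f:
        index = json.load(f)
    out = []
    for entry in index:
        pts = load_point_cloud_ply(index_path.parent / entry["cloud"])
        out.append(CriticalStructure(entry["name"], pts, entry["mantle_mm"]))
    return out
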