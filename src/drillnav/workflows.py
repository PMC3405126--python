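"""End-to-end experiment replicas: accuracy study and drilling sessions.

These orchestrate the library modules into the two study designs:

* ``run_accuracy_study`` — the drill-tracking accuracy experiment on the
  cylinder-and-ball phantom (by default 4 experiments x {pointer, 3, 4,
  5 mm bits} x 19 targets, i.e. 228 drill measurements);
* ``run_drilling_session`` — a seeded virtual surgery on a temporal-bone
  phantom: scripted approach, noisy tracking, voxel-erasure drilling,
  proximity warnings, structure-hit detection, and signed comparison of
  the virtual cavity against the analytic intended cavity.

Every run can write its artifacts plus a manifest (config hash, seed,
version) so identical manifests imply identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dnio
from .drilling import CavityMask, drill_trajectory, erase_at_pose
from .evaluation import (
    mesh_from_mask,
    run_tre_experiment,
    signed_surface_distance,
    export_error_map,
    _shift,
)
from .geometry import NoiseModel, perturb_trajectory
from .phantoms import (
    VoxelVolume,
    _dist_to_segment,
    build_drill_bit,
    make_cylinder_ball_phantom,
    make_temporal_bone_phantom,
    make_trajectory,
    plan_approach,
    sample_capsule_surface,
)
from .proximity import detect_structure_hits, emit_warnings

__all__ = [
    "run_accuracy_study",
    "run_drilling_session",
    "run_decoupling_trial",
    "run_adversarial_trial",
    "run_resolution_comparison",
    "analytic_capsule_mask",
    "outer_surface_points",
]


def _manifest(config: dict, out_dir: Path) -> None:
    from . import __version__

    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "version": __version__,
    }
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)


def run_accuracy_study(
    seed: int = 1,
    n_experiments: int = 4,
    instruments: tuple[str, ...] = ("pointer", "drill_3mm", "drill_4mm", "drill_5mm"),
    sigma_mm: float = 0.8,
    fiducial_sigma_mm: float = 0.0,
    n_cylinders: int = 19,
    out_dir=None,
) -> dict:
    """Replicate the drill-tracking accuracy study on synthetic data.

    Returns a dict with the per-instrument results, the study table, the
    grand mean/SD/max over drill measurements and the drill-measurement
    count (4 x 3 x 19 = 228 at the defaults).
    """
    phantom = make_cylinder_ball_phantom(n_cylinders=n_cylinders, seed=seed)
    noise = NoiseModel(sigma_tip=sigma_mm, sigma_hind=sigma_mm, seed=seed)
    results, table = run_tre_experiment(
        phantom, instruments=instruments, n_experiments=n_experiments,
        noise=noise, fiducial_sigma=fiducial_sigma_mm,
    )
    drill = np.concatenate([r.per_target for r in results if r.instrument != "pointer"])
    summary = {
        "n_drill_measurements": int(drill.size),
        "mean_tre_mm": float(drill.mean()),
        "sd_tre_mm": float(drill.std(ddof=1)),
        "max_tre_mm": float(drill.max()),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "tre_table.csv")
        with open(out_dir / "tre_summary.json", "w") as f:
            json.dump(summary, f, indent=2)
        _manifest({"experiment": "accuracy_study", "seed": seed,
                   "n_experiments": n_experiments, "instruments": list(instruments),
                   "sigma_mm": sigma_mm, "fiducial_sigma_mm": fiducial_sigma_mm,
                   "n_cylinders": n_cylinders}, out_dir)
    return {"results": results, "table": table, **summary}


def analytic_capsule_mask(volume: VoxelVolume, path_points: np.ndarray, radius: float) -> np.ndarray:
    """Voxels whose centres lie within *radius* of the tip polyline."""
    path = np.atleast_2d(np.asarray(path_points, dtype=float))
    spacing = np.diag(volume.affine[:3, :3])
    origin = volume.affine[:3, 3]
    ax = [origin[i] + spacing[i] * np.arange(volume.shape[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    d = np.full(len(pts), np.inf)
    if len(path) == 1:
        d = np.linalg.norm(pts - path[0], axis=1)
    else:
        for p0, p1 in zip(path[:-1], path[1:]):
            d = np.minimum(d, _dist_to_segment(pts, p0, p1))
    return (d <= radius).reshape(volume.shape)


def _analytic_capsule_mesh(volume: VoxelVolume, centers: np.ndarray, radius: float,
                           pitch: float = 0.1) -> "SurfaceMesh":
    """Dense analytic capsule surface as a mesh of bare nodes.

    Assumes a straight centre path (scripted approaches are straight); the
    surface is sampled at *pitch* mm and restricted to the volume bounds.
    """
    from .evaluation import SurfaceMesh

    pts = sample_capsule_surface(centers[0], centers[-1], radius, pitch)
    idx = np.round(volume.world_to_index(pts)).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(volume.shape)), axis=1)
    pts, idx = pts[ok], idx[ok]
    return SurfaceMesh(nodes=pts, faces=np.zeros((0, 4), dtype=np.int64),
                       node_voxels=idx, n_exposed_faces=0, source="real")


def outer_surface_points(volume: VoxelVolume, threshold: float = 500.0) -> np.ndarray:
    """World-mm centres of the boundary voxels of the solid phantom body."""
    solid = volume.data > threshold
    boundary = np.zeros_like(solid)
    for axis in range(3):
        for sign in (-1, 1):
            boundary |= solid & ~_shift(solid, axis, -sign)
    idx = np.argwhere(boundary)
    return volume.index_to_world(idx)


def run_decoupling_trial(
    n_trajectories: int = 1000,
    seed: int = 0,
    e_max_mm: float = 0.8,
    mantle: float = 3.0,
    index_style: str = "isotropic",
    bit_diameter: float = 3.0,
) -> dict:
    """Randomised check of the safety-mantle decoupling property.

    Generates straight descents whose *true* tips always keep at least
    ``mantle - e_max`` clearance from every critical-structure surface
    (the guarantee a warned surgeon who stops in time obeys, with tracking
    error bounded by ``e_max``), drills them at the true poses, and counts
    structure hits. The chosen ``e_max`` keeps the clearance above the bit
    radius plus the voxel diagonal, the geometric condition under which a
    clear tip implies a clear cavity.
    """
    truth = make_temporal_bone_phantom(index_style=index_style, seed=seed, mantle=mantle)
    vol = truth.volume
    pitch = min(0.2, float(vol.spacing.min()))
    bit = build_drill_bit(diameter=bit_diameter, sampling_pitch=pitch)
    clearance = mantle - e_max_mm
    rng = np.random.default_rng((seed * 7919 + 3) % (2**31))
    trees = [s.tree for s in truth.structures]
    top = truth.meta["bone_top_z"] + 2.0
    work = vol.copy()
    hits = 0
    min_clear = np.inf
    done = 0
    while done < n_trajectories:
        x, y = rng.uniform(4.0, vol.index_to_world(np.array(vol.shape) - 1)[0] - 4.0, 2)
        zs = np.arange(top, 2.0, -0.5)
        path = np.column_stack([np.full_like(zs, x), np.full_like(zs, y), zs])
        d = np.min([t.query(path)[0] for t in trees], axis=0)
        ok = d >= clearance
        stop = len(zs) if ok.all() else int(np.argmin(ok))
        if stop < 2:
            continue  # entry already violates clearance; not a valid trial
        traj = make_trajectory(path[:stop][[0, -1]], shaft_dir=(0, 0, 1), speed=8.0)
        min_clear = min(min_clear, float(d[:stop].min()))
        cavity = CavityMask.empty_like(vol)
        for pose in traj:
            erase_at_pose(work, bit, pose, cavity, in_place=True)
        for m in truth.structure_masks.values():
            if np.any(cavity.mask & m):
                hits += 1
                break
        done += 1
    return {"n_trajectories": done, "hits": hits, "min_tip_clearance_mm": min_clear,
            "clearance_mm": clearance, "e_max_mm": e_max_mm, "mantle_mm": mantle}


def run_adversarial_trial(
    n_trajectories: int = 20,
    seed: int = 0,
    e_max_mm: float = 0.8,
    mantle: float = 3.0,
    index_style: str = "isotropic",
    bit_diameter: float = 3.0,
) -> dict:
    """Reckless descents through the nerve: do warnings precede damage?

    Each trajectory aims at the facial-nerve canal with a small random
    lateral offset; the navigation system sees poses with bounded (uniform,
    |error| <= e_max) tracking error. Returns how many trajectories hit a
    structure and, of those, how many raised an ``entered`` warning
    strictly before the first hit.
    """
    truth = make_temporal_bone_phantom(index_style=index_style, seed=seed, mantle=mantle)
    vol = truth.volume
    pitch = min(0.2, float(vol.spacing.min()))
    bit = build_drill_bit(diameter=bit_diameter, sampling_pitch=pitch)
    rng = np.random.default_rng((seed * 6151 + 17) % (2**31))
    n0, n1 = truth.meta["nerve_axis"]
    mid = 0.5 * (np.asarray(n0) + np.asarray(n1))
    top = truth.meta["bone_top_z"] + 2.0
    half_width = e_max_mm / np.sqrt(3.0)
    n_hit = 0
    n_warned_first = 0
    for _ in range(n_trajectories):
        off = rng.uniform(-1.0, 1.0, 2)
        entry = np.array([mid[0] + off[0], mid[1] + off[1], top])
        stop = np.array([entry[0], entry[1], mid[2]])
        traj_true = make_trajectory([entry, stop], shaft_dir=(0, 0, 1), speed=4.0)
        tracked = type(traj_true)(tuple(
            type(p)(t=p.t, tip=p.tip + rng.uniform(-half_width, half_width, 3),
                    hind=p.hind + rng.uniform(-half_width, half_width, 3)).with_shaft_length()
            for p in traj_true
        ))
        _, events = emit_warnings(tracked, truth.structures, record_inside=False)
        entered = [e.t for e in events if e.transition == "entered"]
        work = vol.copy()
        cavity = CavityMask.empty_like(vol)
        t_hit = None
        for pose in traj_true:
            erase_at_pose(work, bit, pose, cavity, in_place=True)
            if any(np.any(cavity.mask & m) for m in truth.structure_masks.values()):
                t_hit = pose.t
                break
        if t_hit is not None:
            n_hit += 1
            if entered and min(entered) < t_hit:
                n_warned_first += 1
    return {"n_trajectories": n_trajectories, "n_hit": n_hit,
            "n_warned_before_hit": n_warned_first}


def run_resolution_comparison(n_seeds: int = 5, seed0: int = 0,
                              bit_diameter: float = 3.0) -> dict:
    """Cavity sampling error across the two scan geometries.

    Drills the same scripted approach (no tracking noise, interpolated
    erasure) into anisotropic-z and isotropic-protocol phantoms over
    ``n_seeds`` seeds and averages the signed extremes of the virtual
    cavity against the analytic intended cavity. The coarse-z geometry is
    expected to show systematically larger errors.
    """
    out: dict = {}
    for style in ("anisotropic", "isotropic"):
        overs, unders, means = [], [], []
        for s in range(seed0, seed0 + n_seeds):
            ses = run_drilling_session(seed=s, index_style=style, approach="safe",
                                       bit_diameter=bit_diameter,
                                       sigma_mm=0.0, interpolate=True)
            c = ses["comparison"]
            overs.append(c.max_over)
            unders.append(abs(c.max_under))
            means.append(c.mean_abs)
        out[style] = {"mean_max_over_mm": float(np.mean(overs)),
                      "mean_max_under_mm": float(np.mean(unders)),
                      "mean_abs_mm": float(np.mean(means)),
                      "n_seeds": n_seeds}
    return out


def run_drilling_session(
    seed: int = 1,
    index_style: str = "isotropic",
    approach: str = "safe",
    bit_shape: str = "sphere",
    bit_diameter: float = 3.0,
    mantle: float = 3.0,
    sigma_mm: float = 0.8,
    stop_on_warning: bool = True,
    interpolate: bool = False,
    entry_exclusion_mm: float = 2.0,
    out_dir=None,
) -> dict:
    """Run one seeded virtual drilling surgery end to end.

    The hand follows the scripted (true) trajectory; the navigation system
    sees a noise-perturbed copy. Warnings are computed from the tracked
    poses; physical damage (structure hits, with first-hit times) from
    drilling at the true poses; the virtual cavity, drilled at the tracked
    poses, is compared against the analytic intended cavity with the entry
    region excluded.
    """
    truth = make_temporal_bone_phantom(index_style=index_style, seed=seed, mantle=mantle)
    vol = truth.volume
    pitch = min(0.2, float(vol.spacing.min()))
    bit = build_drill_bit(shape=bit_shape, diameter=bit_diameter, sampling_pitch=pitch)
    traj_true = plan_approach(truth, style=approach)
    noise = NoiseModel(sigma_tip=sigma_mm, sigma_hind=sigma_mm,
                       seed=(seed * 9973 + 11) % (2**31))
    traj_tracked = perturb_trajectory(traj_true, noise) if sigma_mm > 0 else traj_true

    distances, events = emit_warnings(traj_tracked, truth.structures)
    if stop_on_warning:
        entered_times = [e.t for e in events if e.transition == "entered"]
        if entered_times:
            t_stop = min(entered_times)
            keep_true = tuple(p for p in traj_true if p.t <= t_stop)
            keep_trk = tuple(p for p in traj_tracked if p.t <= t_stop)
            traj_true = type(traj_true)(keep_true)
            traj_tracked = type(traj_tracked)(keep_trk)
            distances = distances[distances.t_s <= t_stop].reset_index(drop=True)
            events = [e for e in events if e.t <= t_stop]

    # virtual cavity: what the interface erases, at tracked poses
    drilled, virtual_cavity, drill_log = drill_trajectory(
        vol, bit, traj_tracked, interpolate=interpolate)

    # in-silico "real" drilling at true poses, with first-hit timing
    real_vol = vol.copy()
    real_cavity = CavityMask.empty_like(vol)
    first_hit: dict[str, float | None] = {n: None for n in truth.structure_masks}
    for pose in traj_true:
        erase_at_pose(real_vol, bit, pose, real_cavity, in_place=True)
        for name, m in truth.structure_masks.items():
            if first_hit[name] is None and np.any(real_cavity.mask & m):
                first_hit[name] = float(pose.t)
    hits = detect_structure_hits(real_cavity, truth.structure_masks)

    # comparison of the virtual cavity against the analytic intended cavity:
    # a spherical bit sweeps a capsule around the path of its centre (one
    # bit radius up the shaft from the tip). The intended surface is kept
    # analytic — densely sampled, resolution-independent — so the grid
    # sampling error of the virtual cavity is actually measurable.
    radius = bit_diameter / 2.0
    centers = np.array([p.tip + radius * p.shaft_direction for p in traj_true])
    intended = analytic_capsule_mask(vol, centers, radius)
    comparison = None
    if intended.any() and virtual_cavity.voxel_count:
        real_mesh = _analytic_capsule_mesh(vol, centers, radius)
        virt_mesh = mesh_from_mask(virtual_cavity.mask, vol.affine, source="virtual")
        excl = (outer_surface_points(vol), entry_exclusion_mm)
        comparison = signed_surface_distance(real_mesh, virt_mesh, intended,
                                             virtual_cavity.mask, entry_exclusion=excl)

    result = {
        "truth": truth,
        "bit": bit,
        "trajectory_true": traj_true,
        "trajectory_tracked": traj_tracked,
        "drilled": drilled,
        "virtual_cavity": virtual_cavity,
        "real_cavity": real_cavity,
        "drill_log": drill_log,
        "distances": distances,
        "events": events,
        "hits": hits,
        "first_hit_times": first_hit,
        "comparison": comparison,
        "mantle_mm": mantle,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        dnio.save_volume(vol, out_dir / "preop.nii.gz")
        dnio.save_volume(drilled, out_dir / "drilled.nii.gz")
        dnio.save_pose_log(traj_tracked, out_dir / "trajectory_tracked.csv")
        drill_log.to_csv(out_dir / "drill_log.csv", index=False)
        distances.to_csv(out_dir / "distances.csv", index=False)
        pd.DataFrame(
            [{"t_s": e.t, "structure": e.structure,
              "distance_mm": e.distance, "transition": e.transition} for e in events]
        ).to_csv(out_dir / "events.csv", index=False)
        hits.to_csv(out_dir / "hits.csv", index=False)
        report = {
            "mantle_mm": mantle,
            "first_hit_times_s": first_hit,
            "n_warnings_entered": sum(e.transition == "entered" for e in events),
        }
        if comparison is not None:
            report.update({
                "mean_abs_mm": comparison.mean_abs,
                "max_over_mm": comparison.max_over,
                "max_under_mm": comparison.max_under,
                "excluded_nodes": comparison.excluded_entry_nodes,
            })
            virt_mesh = mesh_from_mask(virtual_cavity.mask, vol.affine, source="virtual")
            export_error_map(comparison, virt_mesh, out_dir / "error_map.ply")
        with open(out_dir / "cavity_report.json", "w") as f:
            json.dump(report, f, indent=2)
        _manifest({"experiment": "drilling_session", "seed": seed,
                   "index_style": index_style, "approach": approach,
                   "bit": f"{bit_shape}:{bit_diameter}", "mantle_mm": mantle,
                   "sigma_mm": sigma_mm, "stop_on_warning": stop_on_warning,
                   "interpolate": interpolate}, out_dir)
    return result
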