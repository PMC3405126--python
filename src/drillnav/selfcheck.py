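"""Brute-force reference checks of the toolkit's core numerics.

Each routine recomputes a core quantity with an independent, deliberately
naive method (exhaustive scans, analytic membership, closed forms) and
returns both the toolkit's value and the reference value, so that test
suites and validation reports can quantify agreement. The reference
implementations share no code path with the operations they check.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .drilling import drill_trajectory
from .evaluation import compute_tre, maxwell_mean, recover_ball_centers
from .geometry import FiducialSet, register_fiducials
from .phantoms import (
    VoxelVolume,
    _dist_to_segment,
    build_drill_bit,
    make_cylinder_ball_phantom,
    make_trajectory,
)
from .proximity import CriticalStructure, nearest_distance

__all__ = [
    "erasure_oracle_check",
    "distance_oracle_check",
    "registration_recovery_check",
    "tre_recovery_check",
]


def erasure_oracle_check(seed: int = 0, n_cases: int = 2, grid: int = 64,
                         spacing: float = 0.4) -> dict:
    """Swept cavity vs analytic capsule membership on a small grid.

    Drills random straight passes of a spherical bit (dense cloud,
    interpolated poses) and compares the cavity with the set of voxel
    centres inside the capsule swept by the bit centre — the Minkowski sum
    of the path with the bit solid. Agreement is required outside a
    one-voxel-diagonal boundary band.
    """
    rng = np.random.default_rng(seed)
    radius = 1.5
    bit = build_drill_bit("sphere", 2 * radius, 0.15)
    diag = float(np.linalg.norm([spacing] * 3))
    mismatch = 0
    total = 0
    for _ in range(n_cases):
        vol = VoxelVolume(np.full((grid,) * 3, 1500.0, dtype=np.float32),
                          np.diag([spacing, spacing, spacing, 1.0]))
        lo, hi = 8 * spacing, (grid - 9) * spacing
        a, b = rng.uniform(lo, hi, (2, 3))
        traj = make_trajectory([a, b], shaft_dir=(0, 0, 1), speed=8.0)
        _, cavity, _ = drill_trajectory(vol, bit, traj, interpolate=True)

        centers = vol.index_to_world(np.indices(vol.shape).reshape(3, -1).T)
        offset = np.array([0.0, 0.0, radius])  # bit centre rides up the shaft
        d = _dist_to_segment(centers, traj.tips()[0] + offset, traj.tips()[-1] + offset)
        inside = (d <= radius).reshape(vol.shape)
        band = (np.abs(d - radius) <= diag).reshape(vol.shape)
        mismatch += int(np.count_nonzero((inside ^ cavity.mask) & ~band))
        total += int(np.count_nonzero(~band))
    return {"mismatch_voxels": mismatch, "n_voxels_compared": total}


def distance_oracle_check(seed: int = 0, n_tips: int = 1000, n_cloud: int = 10_000) -> dict:
    """KD-tree nearest distances vs an exhaustive all-pairs scan."""
    rng = np.random.default_rng(seed)
    cloud = rng.uniform(0.0, 80.0, (n_cloud, 3))
    structure = CriticalStructure("oracle_cloud", cloud)
    tips = rng.uniform(-10.0, 90.0, (n_tips, 3))
    fast = np.array([nearest_distance(t, structure) for t in tips])
    brute = np.empty(n_tips)
    for i in range(0, n_tips, 100):  # chunked exhaustive scan
        block = tips[i:i + 100]
        brute[i:i + 100] = np.sqrt(
            ((block[:, None, :] - cloud[None, :, :]) ** 2).sum(-1)
        ).min(axis=1)
    return {"max_abs_deviation_mm": float(np.abs(fast - brute).max()), "n_queries": n_tips}


def registration_recovery_check(seed: int = 0, n_transforms: int = 100) -> dict:
    """Rigid registration recovery on noise-free transformed 4-point sets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_transforms):
        phys = rng.uniform(-80.0, 80.0, (4, 3))
        R = Rotation.from_rotvec(rng.uniform(-np.pi, np.pi, 3)).as_matrix()
        t = rng.uniform(-50.0, 50.0, 3)
        img = phys @ R.T + t
        T, fre = register_fiducials(FiducialSet(img, phys))
        residual = float(np.abs(T.apply(phys) - img).max())
        worst = max(worst, residual, fre)
    return {"max_residual_mm": worst, "n_transforms": n_transforms}


def tre_recovery_check(seed: int = 1, sigma: float = 0.8,
                       n_large: int = 10_000) -> dict:
    """Grand-mean TRE against the closed-form mean of the error norm.

    Per-axis Gaussian tracking noise of s.d. sigma makes each TRE a
    Maxwell-distributed variate with mean ``sigma * 2 sqrt(2/pi)``; the
    study-design sample (19 targets x 4 experiments x 3 bits = 228 drill
    measurements) and a large tiled sample are both compared against it.
    """
    from .workflows import run_accuracy_study

    study = run_accuracy_study(seed=seed, sigma_mm=sigma)
    expected = maxwell_mean(sigma)
    phantom = make_cylinder_ball_phantom(seed=seed)
    coms = recover_ball_centers(phantom)
    reps = int(np.ceil(n_large / len(coms)))
    truth = np.tile(coms, (reps, 1))[:n_large]
    touched = np.tile(phantom.target_points, (reps, 1))[:n_large]
    rng = np.random.default_rng((seed * 4099 + 5) % (2**31))
    measured = touched + rng.normal(0.0, sigma, touched.shape)
    large = compute_tre(measured, truth)
    return {
        "mean_tre_228_mm": study["mean_tre_mm"],
        "sd_tre_228_mm": study["sd_tre_mm"],
        "max_tre_228_mm": study["max_tre_mm"],
        "deviation_228_pct": 100.0 * abs(study["mean_tre_mm"] - expected) / expected,
        "mean_tre_large_mm": large.mean,
        "deviation_large_pct": 100.0 * abs(large.mean - expected) / expected,
        "n_large": n_large,
        "maxwell_mean_mm": expected,
    }
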