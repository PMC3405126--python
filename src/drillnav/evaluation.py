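"""Quantitative validation: TRE statistics and cavity-surface comparison.

Two analyses mirror how a navigated-drilling system is validated:

* **Target registration error (TRE)** on the cylinder-and-ball phantom —
  the Euclidean distance between each ball centre recovered from the image
  (region growing + centre of mass) and the tracked touch of that target.
* **Cavity overlap** — the real and virtual drill cavities are recovered
  by subtracting post- from pre-operative images, region-growing the
  difference, meshing the cavity boundary with a node at every boundary
  voxel, and measuring signed nearest-node surface-to-surface distances.
  Positive sign means the virtual cavity overestimates (extends beyond)
  the real one, negative means underestimation; the entry region, where
  agreement is trivially good, is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import FiducialSet, NoiseModel, register_fiducials
from .phantoms import PhantomTruth, VoxelVolume

__all__ = [
    "TREResult",
    "SurfaceMesh",
    "CavityComparison",
    "region_grow",
    "mask_center_of_mass",
    "compute_tre",
    "cavity_from_subtraction",
    "mesh_from_mask",
    "signed_surface_distance",
    "export_error_map",
    "run_tre_experiment",
    "tre_table",
    "maxwell_mean",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def maxwell_mean(sigma: float) -> float:
    """Mean norm of a 3-vector of i.i.d. N(0, sigma^2) components."""
    return sigma * 2.0 * np.sqrt(2.0 / np.pi)


@dataclass(frozen=True)
class TREResult:
    """Per-target registration errors for one instrument in one experiment."""

    per_target: np.ndarray
    instrument: str = "pointer"
    experiment_id: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.per_target, dtype=float)
        if v.ndim != 1 or len(v) == 0 or np.any(v < 0):
            raise ValueError("per_target must be a non-empty 1D array of non-negative mm")
        object.__setattr__(self, "per_target", v)

    @property
    def mean(self) -> float:
        return float(self.per_target.mean())

    @property
    def sd(self) -> float:
        # sample standard deviation (n - 1)
        return float(self.per_target.std(ddof=1)) if len(self.per_target) > 1 else 0.0

    @property
    def max(self) -> float:
        return float(self.per_target.max())


@dataclass
class SurfaceMesh:
    """Cavity boundary with one node at every boundary voxel centre."""

    nodes: np.ndarray
    faces: np.ndarray
    node_voxels: np.ndarray
    n_exposed_faces: int
    source: str = "real"

    def __post_init__(self) -> None:
        if len(self.nodes) == 0:
            raise ValueError("mesh has no nodes")
        if len(self.faces) and self.faces.max() >= len(self.nodes):
            raise ValueError("face references an invalid node")


@dataclass
class CavityComparison:
    """Signed surface-to-surface distances between real and virtual cavities.

    Per-node signed distances are kept per mesh (NaN where a node fell in
    the excluded entry region); ``mean_abs`` averages unsigned distances
    over the analysed nodes of both meshes, and ``max_over``/``max_under``
    are the signed extremes (over- / underestimation).
    """

    real_node_signed: np.ndarray
    virtual_node_signed: np.ndarray
    excluded_entry_nodes: int
    meta: dict = field(default_factory=dict)

    @property
    def per_node_signed(self) -> np.ndarray:
        both = np.concatenate([self.real_node_signed, self.virtual_node_signed])
        return both[np.isfinite(both)]

    @property
    def mean_abs(self) -> float:
        return float(np.abs(self.per_node_signed).mean())

    @property
    def max_over(self) -> float:
        return float(max(self.per_node_signed.max(initial=0.0), 0.0))

    @property
    def max_under(self) -> float:
        return float(min(self.per_node_signed.min(initial=0.0), 0.0))


# ---------------------------------------------------------------------------
# segmentation

def region_grow(volume: VoxelVolume, seed_point, intensity_window) -> np.ndarray:
    """26-connected region growing from a world-mm seed point.

    Returns the maximal 26-connected component of voxels whose intensity
    lies in ``intensity_window = (lo, hi)`` that contains the seed voxel.
    """
    lo, hi = intensity_window
    idx = np.round(volume.world_to_index(np.asarray(seed_point, dtype=float))).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(volume.shape)):
        raise ValueError("seed point lies outside the volume")
    val = float(volume.data[tuple(idx)])
    if not (lo <= val <= hi):
        raise ValueError(f"seed intensity {val:.1f} outside window ({lo}, {hi})")
    window = (volume.data >= lo) & (volume.data <= hi)
    labels, _ = ndimage.label(window, structure=_CONN26)
    return labels == labels[tuple(idx)]


def mask_center_of_mass(mask: np.ndarray, volume: VoxelVolume) -> np.ndarray:
    """Unweighted centre of mass of a binary mask, in world mm."""
    idx = np.argwhere(mask)
    if len(idx) == 0:
        raise ValueError("empty mask")
    return volume.index_to_world(idx.mean(axis=0))


def cavity_from_subtraction(
    pre: VoxelVolume,
    post: VoxelVolume,
    contrast: float | None = None,
) -> np.ndarray:
    """Recover a drill cavity by image subtraction.

    The post-operative image is subtracted from the pre-operative one and
    thresholded at half the bone-background contrast (estimated from the
    pre-operative image unless given); the largest 26-connected component
    of the thresholded difference is the cavity.
    """
    if pre.shape != post.shape or not np.allclose(pre.affine, post.affine):
        raise ValueError("pre and post volumes must share grid and affine")
    diff = pre.data.astype(np.float64) - post.data.astype(np.float64)
    if contrast is None:
        foreground = float(np.percentile(pre.data, 99.0))
        contrast = foreground - pre.background
    thr = 0.5 * contrast
    candidates = diff > thr
    if not candidates.any():
        return np.zeros(pre.shape, dtype=bool)
    labels, n = ndimage.label(candidates, structure=_CONN26)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


# ---------------------------------------------------------------------------
# meshing and signed distances

def _shift(mask: np.ndarray, axis: int, sign: int) -> np.ndarray:
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


def mesh_from_mask(mask: np.ndarray, affine: np.ndarray, source: str = "real") -> SurfaceMesh:
    """Mesh a binary mask with a node at every boundary voxel centre.

    A boundary voxel has at least one of its six face-neighbours outside
    the mask (grid edges count as outside). Quads connect 2x2 patches of
    boundary voxels for visualisation; distance analysis uses the nodes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    affine = np.asarray(affine, dtype=float)

    exposed_total = 0
    boundary = np.zeros_like(mask)
    for axis in range(3):
        for sign in (-1, 1):
            exp = mask & ~_shift(mask, axis, -sign)
            exposed_total += int(np.count_nonzero(exp))
            boundary |= exp

    vox = np.argwhere(boundary)
    nodes = vox @ affine[:3, :3].T + affine[:3, 3]
    idmap = np.full(mask.shape, -1, dtype=np.int64)
    idmap[tuple(vox.T)] = np.arange(len(vox))

    quads = []
    for a1, a2 in ((0, 1), (0, 2), (1, 2)):
        e1 = np.zeros(3, dtype=int); e1[a1] = 1
        e2 = np.zeros(3, dtype=int); e2[a2] = 1
        core = (
            boundary[_sub(None, e1 + e2)]
            & boundary[_sub(e1, e2)]
            & boundary[_sub(e2, e1)]
            & boundary[_sub(e1 + e2, None)]
        )
        cv = np.argwhere(core)
        if len(cv) == 0:
            continue
        i0 = idmap[tuple(cv.T)]
        i1 = idmap[tuple((cv + e1).T)]
        i2 = idmap[tuple((cv + e1 + e2).T)]
        i3 = idmap[tuple((cv + e2).T)]
        quads.append(np.column_stack([i0, i1, i2, i3]))
    faces = np.concatenate(quads, axis=0) if quads else np.zeros((0, 4), dtype=np.int64)
    return SurfaceMesh(nodes=nodes, faces=faces, node_voxels=vox,
                       n_exposed_faces=exposed_total, source=source)


def _sub(lead, trail):
    """Slices selecting the core region offset by *lead* (None = zero offset)."""
    lead = np.zeros(3, dtype=int) if lead is None else lead
    trail = np.zeros(3, dtype=int) if trail is None else trail
    return tuple(
        slice(int(l), None if t == 0 else -int(t)) for l, t in zip(lead, trail)
    )


def signed_surface_distance(
    real: SurfaceMesh,
    virtual: SurfaceMesh,
    real_mask: np.ndarray,
    virtual_mask: np.ndarray,
    entry_exclusion: tuple[np.ndarray, float] | None = None,
) -> CavityComparison:
    """Signed nearest-node distances between two cavity surfaces.

    For every analysed node of each mesh the unsigned distance is the
    nearest-node distance to the other mesh. The sign is positive where
    the virtual cavity extends beyond the real one (a virtual node outside
    the real mask, or a real node inside the virtual mask) and negative
    for the reverse. ``entry_exclusion = (surface_points, radius_mm)``
    drops nodes within ``radius_mm`` of the given outer-surface cloud.
    """
    real_mask = np.asarray(real_mask, dtype=bool)
    virtual_mask = np.asarray(virtual_mask, dtype=bool)
    if real_mask.shape != virtual_mask.shape:
        raise ValueError("masks must share a grid")

    excl_tree = None
    radius = 0.0
    if entry_exclusion is not None:
        pts, radius = entry_exclusion
        excl_tree = cKDTree(np.asarray(pts, dtype=float))

    def analyse(mesh: SurfaceMesh, other: SurfaceMesh, other_mask: np.ndarray,
                inside_is_over: bool) -> tuple[np.ndarray, int]:
        d, _ = cKDTree(other.nodes).query(mesh.nodes)
        inside = other_mask[tuple(mesh.node_voxels.T)]
        over = inside if inside_is_over else ~inside
        signed = np.where(over, d, -d)
        n_excl = 0
        if excl_tree is not None:
            de, _ = excl_tree.query(mesh.nodes)
            drop = de <= radius
            n_excl = int(np.count_nonzero(drop))
            signed = np.where(drop, np.nan, signed)
        return signed, n_excl

    # real node inside the virtual mask -> virtual cavity reaches past it: over
    real_signed, n1 = analyse(real, virtual, virtual_mask, inside_is_over=True)
    # virtual node outside the real mask -> virtual cavity extends beyond: over
    virt_signed, n2 = analyse(virtual, real, real_mask, inside_is_over=False)
    if not np.isfinite(np.concatenate([real_signed, virt_signed])).any():
        raise ValueError("all nodes excluded; nothing to analyse")
    return CavityComparison(
        real_node_signed=real_signed,
        virtual_node_signed=virt_signed,
        excluded_entry_nodes=n1 + n2,
        meta={
            "mean_convention": "unsigned distances averaged over both meshes' analysed nodes",
            "sign_convention": "+ = virtual overestimates the cavity",
        },
    )


# error-to-colour bands (mm): matched to a diverging under/over legend
_BANDS = [
    (-np.inf, -2.0, (165, 0, 38)),      # underestimation beyond 2 mm
    (-2.0, -1.0, (244, 109, 67)),       # underestimation 1-2 mm
    (-1.0, 1.0, (26, 152, 80)),         # |error| under 1 mm
    (1.0, 2.0, (116, 173, 209)),        # overestimation 1-2 mm
    (2.0, np.inf, (49, 54, 149)),       # overestimation beyond 2 mm
]
_EXCLUDED_RGB = (128, 128, 128)


def error_band_color(d: float) -> tuple[int, int, int]:
    """RGB for one signed distance under the fixed diverging band map."""
    if not np.isfinite(d):
        return _EXCLUDED_RGB
    for _, hi, rgb in _BANDS:
        if d < hi:
            return rgb
    return _BANDS[-1][2]


def export_error_map(cmp: CavityComparison, mesh: SurfaceMesh, path) -> str:
    """Write a colour-coded ASCII PLY of the signed-distance map.

    Per-vertex RGB follows the fixed diverging bands at +-1 and +-2 mm;
    excluded (entry-region) nodes are grey. The legend is embedded as PLY
    comment lines, so the file is self-describing and re-readable by any
    PLY loader.
    """
    signed = cmp.real_node_signed if mesh.source == "real" else cmp.virtual_node_signed
    if len(signed) != len(mesh.nodes):
        raise ValueError("comparison does not cover this mesh's nodes")
    colors = np.array([error_band_color(float(d)) for d in signed], dtype=int)
    path = str(path)
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\n")
        f.write("comment signed surface-to-surface distance map (mm)\n")
        f.write("comment sign: + virtual cavity overestimates, - underestimates\n")
        for lo, hi, rgb in _BANDS:
            f.write(f"comment band {lo} .. {hi} mm -> rgb {rgb[0]} {rgb[1]} {rgb[2]}\n")
        f.write(f"comment excluded entry nodes -> rgb {_EXCLUDED_RGB[0]} {_EXCLUDED_RGB[1]} {_EXCLUDED_RGB[2]}\n")
        f.write(f"element vertex {len(mesh.nodes)}\n")
        f.write("property float x\nproperty float y\nproperty float z\n")
        f.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        f.write(f"element face {len(mesh.faces)}\n")
        f.write("property list uchar int vertex_indices\nend_header\n")
        for p, c in zip(mesh.nodes, colors):
            f.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {c[0]} {c[1]} {c[2]}\n")
        for q in mesh.faces:
            f.write("4 " + " ".join(str(int(v)) for v in q) + "\n")
    return path


# ---------------------------------------------------------------------------
# TRE experiment replica

def compute_tre(measured, truth, instrument: str = "pointer", experiment_id: int = 1) -> TREResult:
    """Per-target Euclidean point-to-point registration errors."""
    m = np.atleast_2d(np.asarray(measured, dtype=float))
    t = np.atleast_2d(np.asarray(truth, dtype=float))
    if m.shape != t.shape:
        raise ValueError("measured and truth must pair up")
    d = np.linalg.norm(m - t, axis=1)
    return TREResult(per_target=d, instrument=instrument, experiment_id=experiment_id)


def recover_ball_centers(truth: PhantomTruth) -> np.ndarray:
    """Region-grow each ball shell and return its centre of mass (world mm)."""
    window = truth.meta["shell_window"]
    seeds = truth.meta["ball_seed_points"]
    return np.array([
        mask_center_of_mass(region_grow(truth.volume, s, window), truth.volume)
        for s in seeds
    ])


def run_tre_experiment(
    phantom: PhantomTruth,
    instruments: tuple[str, ...] = ("pointer", "drill_3mm", "drill_4mm", "drill_5mm"),
    n_experiments: int = 4,
    noise: NoiseModel | None = None,
    fiducial_sigma: float = 0.0,
) -> tuple[list[TREResult], pd.DataFrame]:
    """Replicate the drill-tracking accuracy study on the ball phantom.

    Each experiment performs a fresh registration (optionally with
    fiducial-designation noise), then touches every target once per
    instrument with per-axis Gaussian tracking noise; the image-truth
    positions come from region growing the ball shells and taking centres
    of mass. Returns the per-instrument results and a study table
    (one row per experiment, mean and SD columns per instrument, plus
    Average and Maximum rows).
    """
    if noise is None:
        noise = NoiseModel()
    truth_centers = recover_ball_centers(phantom)
    targets = phantom.target_points
    results: list[TREResult] = []
    for e in range(1, n_experiments + 1):
        rng = np.random.default_rng([int(noise.seed) % (2**31), e])
        phys = phantom.fiducials.physical_points
        if fiducial_sigma > 0:
            phys = phys + rng.normal(0.0, fiducial_sigma, phys.shape)
        fid = FiducialSet(image_points=phantom.fiducials.image_points,
                          physical_points=phys)
        transform, _ = register_fiducials(fid)
        # registration maps tracker space to image space; the synthetic
        # phantom shares one frame, so noise-free fiducials give identity
        for inst in instruments:
            touched = targets + rng.normal(0.0, noise.sigma_tip, targets.shape)
            measured = transform.apply(touched)
            results.append(compute_tre(measured, truth_centers,
                                       instrument=inst, experiment_id=e))
    return results, tre_table(results, instruments, n_experiments)


def tre_table(results: list[TREResult], instruments: tuple[str, ...],
              n_experiments: int) -> pd.DataFrame:
    """Arrange TRE results as an accuracy-study table.

    Rows are experiments 1..n plus Average and Maximum; columns alternate
    per-instrument mean and SD (max row leaves SD blank).
    """
    cols: dict[str, list] = {}
    by = {(r.instrument, r.experiment_id): r for r in results}
    for inst in instruments:
        means, sds = [], []
        for e in range(1, n_experiments + 1):
            r = by.get((inst, e))
            means.append(r.mean if r else np.nan)
            sds.append(r.sd if r else np.nan)
        pooled = np.concatenate([by[(inst, e)].per_target
                                 for e in range(1, n_experiments + 1)
                                 if (inst, e) in by])
        cols[inst] = means + [float(pooled.mean()), float(pooled.max())]
        cols[f"{inst}_sd"] = sds + [float(pooled.std(ddof=1)), np.nan]
    index = [str(e) for e in range(1, n_experiments + 1)] + ["Average", "Maximum"]
    return pd.DataFrame(cols, index=index)
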