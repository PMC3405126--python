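# Methods

This note records the models, numerical conventions and design choices
behind `drillnav`, and what the synthetic experiments do and do not show.

## Coordinate model and tool geometry

All public coordinates are world millimetres. A `VoxelVolume` couples a
3D intensity grid to a 4×4 affine mapping 0-based voxel indices to the
world coordinates of voxel centres; synthetic volumes use diagonal
(axis-aligned) affines with a non-trivial origin, but all operations go
through the affine and accept general invertible ones.

A tracked instrument is a tip plus a hind point fixed exactly 100 mm up
the shaft; every operation that moves a pose (calibration, noise
perturbation, interpolation) re-normalises the hind to 100 mm. Divot
calibration applies `tip_offset = tip_travel − divot_depth` along the
unit shaft vector (tip → hind): a bit too wide to reach the divot bottom
travels further than the divot is deep, and the surplus shifts the
modelled tip back up the shaft.

Simulated tracking error is per-axis Gaussian noise on tip and hind
(`NoiseModel`, default σ = 0.8 mm per axis, explicit integer seed). This
deliberately collapses the separate physical error sources of an optical
navigation chain (fiducial designation in image and on the phantom,
registration, camera measurement, tip calibration) into two sigmas: the
validation targets distributional behaviour, not error attribution. The
default was chosen so that the implied mean error norm,
σ·2√(2/π) ≈ 1.28 mm, sits in the range reported for tracked drills in
the operating room (≈ 1.3 mm mean TRE). Fiducial-designation noise is a
separate, by default zero, sigma in the TRE replica.

## Registration and TRE

`register_fiducials` solves the orthogonal Procrustes problem with the
SVD (Kabsch) construction, mapping tracker-space points into image space;
a reflection is corrected by sign-flipping the smallest singular
direction. FRE is the RMS residual after alignment (whether a navigation
machine displays RMS or mean residual is vendor-specific; RMS is chosen
and stated here). Collinear fiducial configurations are rejected via the
singular values of the centred point matrix.

Image-truth targets on the accuracy phantom are recovered exactly as a
validation pipeline would: region-grow the hollow ball shell around each
target (the shells carry a distinct intensity, so a fixed window
segments them under the default intensity noise), then take the
unweighted centre of mass. With zero tracking noise the residual TRE is
pure discretisation and stays below half a voxel diagonal. TRE is the
per-target Euclidean distance; summary SDs use the sample convention
(n − 1), and the study table pools per-measurement values across
experiments (rows = experiments, columns = instrument mean/SD, plus
Average and Maximum rows).

## Virtual drilling

The drill bit is an analytic solid (sphere, or sphere + cylindrical neck
for the match-head shape) point-sampled on a regular grid at a pitch
finer than the image voxel spacing (default 0.2 mm, reduced to the voxel
spacing when drilling the 0.18 mm-plane geometry). The local frame puts
the tip at the origin with the shaft along +z; a shaft stub is optional
and off by default, so the default sphere cloud lies entirely within the
bit envelope. Real bits would be scanned at high resolution; analytic
solids replace the scan while preserving the cloud/erasure mechanism.

Posing uses the minimal (roll-free) rotation taking the local shaft axis
to the pose's shaft direction. The axial roll of a spinning bit is
physically irrelevant; for discretely sampled clouds two rolls can
differ in voxels whose cubes barely clip the sphere surface, so
roll-invariance holds exactly only outside a one-voxel boundary band.

Erasure maps each posed cloud point through the inverse affine and
rounds half-away-from-zero to the nearest voxel index (ties are
measure-zero; the rule is fixed for determinism). In-bounds voxels take
the background intensity and join an explicit cavity mask; out-of-bounds
points are skipped silently (normal during the approach). Erasure is
idempotent and order-independent; by default it works on a copy, with an
in-place flag for accumulation loops.

Interpolation between pose samples is **off** by default: erasing only
at received samples is the faithful behaviour of a system fed ~0.16 s
pose updates, and fast hand motion then leaves scallops. The `interpolate`
flag inserts intermediate poses so successive tips differ by at most half
the finest voxel spacing, producing the gap-free swept cavity the
analytic oracles assume.

## Distance emission and the safety mantle

Critical structures are surface point clouds at ≤ 0.1 mm pitch — either
analytic surfaces from the phantom generator (exact to the generating
shape) or exposed voxel faces of a segmentation mask sampled at the same
pitch. Distance is measured from the tip point only, to the cloud (not
the underlying continuous surface); at 0.1 mm sampling the cloud-vs-
surface discrepancy is ≤ 0.05 mm, below every tolerance used. A KD-tree
accelerates queries but returns the exact minimum.

Warnings trigger on a strict crossing (distance < mantle from
≥ mantle), with no hysteresis band; while the tip dwells inside the
mantle an `inside` event is emitted per pose (continuous re-emission),
and `entered`/`exited` strictly alternate per structure. The default
mantle is 3 mm.

The decoupling property — the mantle, not the structure size, absorbs
the tracking error — is verified by simulation: trajectories whose true
tips keep at least `mantle − e_max` clearance from every structure
surface, with tracking error bounded by `e_max`, must never damage a
structure. Because damage is assessed on the erased *cavity*, the
guarantee is geometric only when the clearance also exceeds the bit
radius plus a voxel diagonal; the trial therefore uses `e_max = 0.8 mm`
(the tracking-noise scale used throughout), giving 2.2 mm clearance
against a 1.5 mm bit radius. Larger bounded errors would need a thicker
mantle in the same proportion — which is precisely the mechanism the
property demonstrates.

## Cavity comparison

Cavities are recovered the way a validation study would: subtract the
post-operative from the pre-operative image, threshold at half the
bone-background contrast (estimated from the pre-operative image), and
keep the largest 26-connected component. Synthetic post-operative
volumes share the pre-operative frame, so no affine re-registration is
needed or provided.

Meshing places a node at every boundary voxel centre (a mask voxel with
at least one of six face-neighbours outside; grid edges count as
outside) — "no loss of resolution" meshing rather than marching cubes,
which would move nodes off voxel centres. Quads over 2×2 boundary
patches are attached for visualisation only; analysis uses the nodes.

Signed distances: for every analysed node of each mesh the unsigned
value is the nearest-node distance to the other mesh; the sign is
positive where the virtual cavity extends beyond the real one (a virtual
node outside the real mask, or a real node inside the virtual mask) and
negative for the reverse. This containment rule operationalises
"overestimation = the interface shows bone as removed that is still
there". The mean is taken over unsigned values of both meshes' analysed
nodes (signed means near-cancel and would hide the error magnitude);
`max_over`/`max_under` are the signed extremes. The entry region — nodes
within 2 mm (configurable) of the phantom's outer surface — is excluded,
since agreement there is trivially good; the exclusion extent is a
package choice, stated in the output metadata. Error maps are ASCII PLY
with per-vertex RGB from a fixed diverging band palette (±1, ±2 mm
bands; grey for excluded nodes) and the legend embedded as comments.

In end-to-end sessions the virtual cavity (drilled at tracked poses) is
compared against the *analytic intended cavity*: the capsule swept by
the bit centre along the true path, kept as a densely sampled analytic
surface rather than a same-grid mask. Two masks on the same grid
quantize identically and would hide the grid-sampling error that is the
point of the comparison. This is how the resolution mechanism appears:
over seeded sessions with no tracking noise and interpolated erasure,
the coarse-z geometry (0.18×0.18×1.0 mm) shows mean max over/under
errors of ≈ 0.50/0.52 mm against ≈ 0.29/0.34 mm for the
0.34×0.34×0.4 mm protocol — errors largest along the axis of lowest
resolution, the reason isotropic high-resolution scans are preferred for
exposure visualization.

## Synthetic phantoms

The generator emulates the *mechanics* of the physical test objects, not
their radiological appearance. Intensities are fixed HU-like constants
(air −1000, silicone 100, ball shells 800, bone 1500, metal 3000) with
additive Gaussian texture noise (σ = 10 by default) so segmentation
windows are reproducible; voxels are painted by centre membership with
no partial-volume model. Cylinder heights (25–55 mm), structure
placements (±2 mm) and orientations (±5°) jitter per seed, mimicking
hand-made phantoms that each differ slightly. Scripted approaches are
straight vertical descents (safe: over the tumour; reckless: through the
nerve canal), so analytic capsule surfaces are exact.

Consequences: passing tests show the geometry, bookkeeping and
statistics of the pipeline are right, and that the warning mechanism's
guarantees hold under the stated noise model. They do not show
robustness to real CT texture, partial-volume effects, mastoid air
cells, soft-tissue appearance, segmentation error on real anatomy, or
human factors — the phantoms are explicitly simpler than a real temporal
bone.

## Problem sizes and tolerances

Default problem sizes are chosen to keep a full validation run at a few
minutes on one CPU: 40×40×32 mm temporal blocks (≈ 1–2 M voxels),
64³ oracle grids, 1,000-trajectory decoupling trials, 5 seeds per scan
geometry, 10,000-draw statistical checks. Exact-arithmetic claims are
tested at 1e-9–1e-12 mm; discretisation-bound claims at half to one
voxel diagonal; statistical claims at 2–5% with fixed seeds. The
registration brute-force oracle is a multi-start rotation-vector
least-squares fit independent of the SVD solver.

## Known limitations

* Whole-bit proximity (distance from the full cloud, not just the tip)
  is not implemented; the tip-only rule matches the modelled interface.
* `cavity_from_subtraction` assumes a shared image frame; registering a
  physically re-scanned volume is out of scope.
* Boundary-voxel meshes are not watertight manifolds; they are distance
  carriers with visualisation faces.
* The NIfTI writer stores the background intensity in the header
  description field; foreign NIfTI files fall back to the data minimum.
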