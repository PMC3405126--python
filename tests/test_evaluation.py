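"""Region growing, TRE statistics, cavity recovery, meshing, signed distances."""

import numpy as np
import pytest

from drillnav import (
    CavityMask,
    NoiseModel,
    VoxelVolume,
    build_drill_bit,
    cavity_from_subtraction,
    compute_tre,
    erase_at_pose,
    export_error_map,
    make_cylinder_ball_phantom,
    mask_center_of_mass,
    maxwell_mean,
    mesh_from_mask,
    region_grow,
    run_tre_experiment,
    signed_surface_distance,
)
from drillnav.evaluation import TREResult, error_band_color


def vol_from(data, spacing=(1.0, 1.0, 1.0), background=-1000.0):
    aff = np.diag([*spacing, 1.0])
    return VoxelVolume(np.asarray(data, np.float32), aff, background)


class TestRegionGrow:
    def test_uniform_block(self):
        v = vol_from(np.full((6, 6, 6), 100.0))
        mask = region_grow(v, [3.0, 3.0, 3.0], (50, 150))
        assert mask.all()

    def test_two_separated_blobs(self):
        data = np.full((12, 6, 6), -1000.0)
        data[1:4] = 100.0
        data[8:11] = 100.0
        v = vol_from(data)
        mask = region_grow(v, [2.0, 3.0, 3.0], (50, 150))
        assert mask[1:4].all() and not mask[8:11].any()

    def test_seed_outside_window_rejected(self):
        v = vol_from(np.full((4, 4, 4), 100.0))
        with pytest.raises(ValueError):
            region_grow(v, [1.0, 1.0, 1.0], (500, 600))


class TestComputeTre:
    def test_exact_match_gives_zero(self):
        pts = np.random.default_rng(0).uniform(0, 10, (5, 3))
        res = compute_tre(pts, pts)
        assert res.mean == res.max == 0.0

    def test_three_four_five(self):
        res = compute_tre([[3.0, 4.0, 0.0]], [[0.0, 0.0, 0.0]])
        assert res.per_target[0] == pytest.approx(5.0, abs=1e-12)

    def test_mean_matches_maxwell_oracle(self):
        rng = np.random.default_rng(1)
        truth = rng.uniform(0, 100, (19, 3))
        sigma = 0.8
        draws = np.concatenate([
            compute_tre(truth + rng.normal(0, sigma, truth.shape), truth).per_target
            for _ in range(200)
        ])
        assert draws.mean() == pytest.approx(maxwell_mean(sigma), rel=0.02)

    def test_summary_consistent_with_per_target(self):
        rng = np.random.default_rng(2)
        res = TREResult(per_target=rng.uniform(0, 3, 19))
        assert res.mean == pytest.approx(res.per_target.mean(), abs=1e-12)
        assert res.sd == pytest.approx(res.per_target.std(ddof=1), abs=1e-12)
        assert res.max == pytest.approx(res.per_target.max(), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_tre(np.zeros((3, 3)), np.zeros((4, 3)))


class TestCavityFromSubtraction:
    @pytest.fixture()
    def bone(self):
        return vol_from(np.full((48, 48, 48), 1500.0), spacing=(0.4, 0.4, 0.4))

    def test_identical_images_empty(self, bone):
        assert not cavity_from_subtraction(bone, bone.copy()).any()

    def test_recovers_erased_capsule_exactly(self, bone, pose_factory):
        bit = build_drill_bit("sphere", 4.0, 0.2)
        post, cav, _ = erase_at_pose(bone, bit, pose_factory([9.6, 9.6, 9.6]))
        rec = cavity_from_subtraction(bone, post)
        assert np.array_equal(rec, cav.mask)

    def test_robust_to_intensity_noise(self, bone, pose_factory):
        rng = np.random.default_rng(7)
        bit = build_drill_bit("sphere", 4.0, 0.2)
        post, cav, _ = erase_at_pose(bone, bit, pose_factory([9.6, 9.6, 9.6]))
        noisy_pre = bone.copy()
        noisy_pre.data += rng.normal(0, 20, bone.shape).astype(np.float32)
        noisy_post = post.copy()
        noisy_post.data += rng.normal(0, 20, bone.shape).astype(np.float32)
        rec = cavity_from_subtraction(noisy_pre, noisy_post)
        dice = 2 * np.sum(rec & cav.mask) / (rec.sum() + cav.mask.sum())
        assert dice > 0.99

    def test_grid_mismatch_rejected(self, bone):
        other = vol_from(np.full((48, 48, 48), 1500.0), spacing=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            cavity_from_subtraction(bone, other)


class TestMeshFromMask:
    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        mesh = mesh_from_mask(mask, np.eye(4))
        assert len(mesh.nodes) == 1
        assert mesh.n_exposed_faces == 6

    def test_cube_has_26_boundary_nodes(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        mesh = mesh_from_mask(mask, np.eye(4))
        assert len(mesh.nodes) == 26

    @pytest.mark.parametrize("seed", range(5))
    def test_node_count_matches_bruteforce_boundary_scan(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((8, 8, 8)) > 0.5
        if not mask.any():
            mask[4, 4, 4] = True
        mesh = mesh_from_mask(mask, np.eye(4))
        count = 0
        for idx in np.argwhere(mask):
            boundary = False
            for ax in range(3):
                for d in (-1, 1):
                    nb = idx.copy()
                    nb[ax] += d
                    if (nb < 0).any() or (nb >= 8).any() or not mask[tuple(nb)]:
                        boundary = True
            count += boundary
        assert len(mesh.nodes) == count

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mesh_from_mask(np.zeros((3, 3, 3), bool), np.eye(4))


def sphere_mask(shape, spacing, center, r):
    idx = np.indices(shape).reshape(3, -1).T * np.asarray(spacing)
    return (np.linalg.norm(idx - center, axis=1) <= r).reshape(shape)


class TestSignedSurfaceDistance:
    def test_identical_cavities_all_zero(self):
        mask = sphere_mask((32, 32, 32), (0.4, 0.4, 0.4), [6.4, 6.4, 6.4], 3.0)
        aff = np.diag([0.4, 0.4, 0.4, 1.0])
        mesh = mesh_from_mask(mask, aff)
        cmp = signed_surface_distance(mesh, mesh_from_mask(mask, aff, "virtual"), mask, mask)
        assert cmp.mean_abs == 0.0
        assert cmp.max_over == 0.0 and cmp.max_under == 0.0

    def test_one_voxel_dilation(self):
        from scipy.ndimage import binary_dilation

        spacing = 0.4
        aff = np.diag([spacing, spacing, spacing, 1.0])
        real = sphere_mask((32, 32, 32), (spacing,) * 3, [6.4, 6.4, 6.4], 3.0)
        virt = binary_dilation(real)  # 6-connected, one voxel outward
        cmp = signed_surface_distance(
            mesh_from_mask(real, aff), mesh_from_mask(virt, aff, "virtual"), real, virt)
        assert cmp.max_over == pytest.approx(spacing, abs=spacing / 2)
        assert cmp.max_under == pytest.approx(0.0, abs=1e-9)

    def test_one_mm_translation(self):
        spacing = 0.5
        aff = np.diag([spacing, spacing, spacing, 1.0])
        real = sphere_mask((40, 40, 40), (spacing,) * 3, [10.0, 10.0, 10.0], 4.0)
        virt = np.roll(real, 2, axis=0)  # exactly 1 mm shift
        cmp = signed_surface_distance(
            mesh_from_mask(real, aff), mesh_from_mask(virt, aff, "virtual"), real, virt)
        diag = np.sqrt(3) * spacing
        assert cmp.max_over == pytest.approx(1.0, abs=diag)
        assert cmp.max_under == pytest.approx(-1.0, abs=diag)

    def test_swap_symmetry_of_extremes(self):
        from scipy.ndimage import binary_dilation

        spacing = 0.5
        aff = np.diag([spacing, spacing, spacing, 1.0])
        a = sphere_mask((32, 32, 32), (spacing,) * 3, [8.0, 8.0, 8.0], 3.5)
        b = binary_dilation(np.roll(a, 1, axis=1))
        ma, mb = mesh_from_mask(a, aff, "real"), mesh_from_mask(b, aff, "virtual")
        fwd = signed_surface_distance(ma, mb, a, b)
        rev = signed_surface_distance(mb, ma, b, a)
        diag = np.sqrt(3) * spacing
        assert abs(fwd.max_over) == pytest.approx(abs(rev.max_under), abs=diag)
        assert abs(fwd.max_under) == pytest.approx(abs(rev.max_over), abs=diag)

    def test_entry_exclusion_counts_nodes(self):
        mask = sphere_mask((32, 32, 32), (0.5,) * 3, [8.0, 8.0, 8.0], 3.0)
        aff = np.diag([0.5, 0.5, 0.5, 1.0])
        mesh = mesh_from_mask(mask, aff)
        plane = np.column_stack([np.zeros(100), np.linspace(0, 16, 100), np.full(100, 8.0)])
        cmp = signed_surface_distance(mesh, mesh_from_mask(mask, aff, "virtual"),
                                      mask, mask, entry_exclusion=(plane, 6.0))
        assert cmp.excluded_entry_nodes > 0
        assert np.isnan(cmp.real_node_signed).sum() > 0


class TestErrorMap:
    def test_band_assignment(self):
        assert error_band_color(0.0) == (26, 152, 80)
        assert error_band_color(1.5) == (116, 173, 209)  # 1-2 mm overestimation band
        assert error_band_color(-1.5) == (244, 109, 67)
        assert error_band_color(2.5) == (49, 54, 149)

    def test_ply_round_trip(self, tmp_path):
        import trimesh

        mask = sphere_mask((16, 16, 16), (0.5,) * 3, [4.0, 4.0, 4.0], 2.0)
        aff = np.diag([0.5, 0.5, 0.5, 1.0])
        mesh = mesh_from_mask(mask, aff)
        cmp = signed_surface_distance(mesh, mesh_from_mask(mask, aff, "virtual"), mask, mask)
        path = export_error_map(cmp, mesh, tmp_path / "map.ply")
        loaded = trimesh.load(path, process=False)
        assert len(loaded.vertices) == len(mesh.nodes)
        expected = np.array([error_band_color(d) for d in cmp.real_node_signed])
        assert np.array_equal(np.asarray(loaded.visual.vertex_colors)[:, :3], expected)


@pytest.fixture(scope="module")
def phantom():
    return make_cylinder_ball_phantom(seed=9)


class TestRunTreExperiment:
    def test_design_counts_and_table_shape(self, phantom):
        results, table = run_tre_experiment(phantom, noise=NoiseModel(0.8, 0.8, seed=1))
        drill = [r for r in results if r.instrument != "pointer"]
        assert sum(len(r.per_target) for r in drill) == 228
        assert list(table.index) == ["1", "2", "3", "4", "Average", "Maximum"]
        for inst in ("pointer", "drill_3mm", "drill_4mm", "drill_5mm"):
            assert inst in table.columns and f"{inst}_sd" in table.columns

    def test_zero_noise_bounded_by_discretisation(self, phantom):
        results, _ = run_tre_experiment(phantom, noise=NoiseModel(0.0, 0.0, seed=1),
                                        n_experiments=1)
        half_diag = 0.5 * np.linalg.norm(phantom.volume.spacing)
        for r in results:
            assert r.max <= half_diag
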