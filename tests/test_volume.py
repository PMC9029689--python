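import numpy as np
import pytest

from _oracles import brute_force_boundary
from hybridsurf import (
    DegenerateMaskError,
    SegmentationVolume,
    contours_to_points,
    estimate_normals,
    extract_boundary_points,
    load_mask,
    save_mask,
)
from hybridsurf.volume import BoundaryPointSet, UnsupportedVolumeError


def make_volume(grid, spacing=(1, 1, 1), origin=(0, 0, 0)):
    return SegmentationVolume(np.asarray(grid, dtype=np.uint8), spacing, origin)


class TestSegmentationVolume:
    def test_rejects_non_binary_values(self):
        with pytest.raises(ValueError, match="0 or 1"):
            make_volume(np.full((3, 3, 3), 2))

    def test_rejects_non_positive_spacing(self):
        with pytest.raises(ValueError, match="spacing"):
            make_volume(np.zeros((3, 3, 3)), spacing=(1, 0, 1))

    def test_world_coordinates_use_voxel_center_convention(self):
        vol = make_volume(np.zeros((4, 4, 4)), spacing=(1, 1, 1.3), origin=(2, 0, -1))
        np.testing.assert_allclose(
            vol.world_coordinates([[1, 2, 3]]), [[3.0, 2.0, -1.0 + 3.9]]
        )


class TestMaskIO:
    @pytest.mark.parametrize("ext", [".nii.gz", ".nrrd"])
    def test_round_trip_preserves_grid_and_geometry(self, tmp_path, ext, sphere_phantom):
        _, vol, _ = sphere_phantom
        path = tmp_path / f"mask{ext}"
        save_mask(vol, path)
        back = load_mask(path)
        np.testing.assert_array_equal(back.grid, vol.grid)
        np.testing.assert_allclose(back.spacing, vol.spacing)
        np.testing.assert_allclose(back.origin, vol.origin, atol=1e-6)

    def test_values_are_binarized_above_half(self, tmp_path):
        import nibabel as nib

        data = np.zeros((4, 4, 4), dtype=np.uint8)
        data[1:3, 1:3, 1:3] = 255
        path = tmp_path / "labels.nii"
        nib.save(nib.Nifti1Image(data, np.eye(4)), path)
        vol = load_mask(path)
        assert set(np.unique(vol.grid)) == {0, 1}
        assert vol.grid.sum() == 8

    def test_empty_mask_loads_but_boundary_errors(self, tmp_path):
        import nibabel as nib

        path = tmp_path / "empty.nii"
        nib.save(nib.Nifti1Image(np.zeros((3, 3, 3), dtype=np.uint8), np.eye(4)), path)
        vol = load_mask(path)
        assert vol.grid.sum() == 0
        with pytest.raises(DegenerateMaskError):
            extract_boundary_points(vol)

    def test_4d_volume_rejected_naming_shape(self, tmp_path):
        import nibabel as nib

        path = tmp_path / "4d.nii"
        nib.save(nib.Nifti1Image(np.zeros((3, 3, 3, 2), dtype=np.uint8), np.eye(4)), path)
        with pytest.raises(UnsupportedVolumeError, match="3, 3, 3, 2"):
            load_mask(path)

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises((IOError, OSError, FileNotFoundError)):
            load_mask(tmp_path / "nope.nii.gz")


class TestBoundaryExtraction:
    def test_single_voxel_gives_one_point_at_its_center(self):
        grid = np.zeros((3, 3, 3))
        grid[1, 1, 1] = 1
        vol = make_volume(grid, spacing=(2, 2, 2), origin=(1, 1, 1))
        with pytest.warns(UserWarning, match="arbitrary normal"):
            pts = extract_boundary_points(vol, sigma=1.0)
        assert len(pts) == 1
        np.testing.assert_allclose(pts.points[0], [3, 3, 3])

    def test_solid_block_boundary_excludes_interior(self):
        grid = np.zeros((5, 5, 5))
        grid[1:4, 1:4, 1:4] = 1
        pts = extract_boundary_points(make_volume(grid))
        assert len(pts) == 26  # all 27 block voxels except the center

    def test_full_grid_is_degenerate(self):
        with pytest.raises(DegenerateMaskError):
            extract_boundary_points(make_volume(np.ones((3, 3, 3))))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        grid = (rng.random((16, 16, 16)) < 0.4).astype(np.uint8)
        if grid.sum() in (0, grid.size):
            pytest.skip("degenerate draw")
        pts = extract_boundary_points(make_volume(grid))
        expected = brute_force_boundary(grid)
        got = pts.source_voxel[np.lexsort(pts.source_voxel.T[::-1])]
        exp = expected[np.lexsort(expected.T[::-1])]
        np.testing.assert_array_equal(got, exp)

    def test_border_touching_voxels_are_boundary(self, sphere_phantom):
        grid = np.zeros((3, 3, 3))
        grid[0, :, :] = 1
        pts = extract_boundary_points(make_volume(grid))
        assert len(pts) == 9  # the whole slab face touches out-of-bounds background


class TestNormals:
    def test_half_space_normals_point_up(self):
        grid = np.zeros((8, 8, 8))
        grid[:, :, :4] = 1  # foreground where z < 4
        pts = extract_boundary_points(make_volume(grid), sigma=1.0)
        inner = pts.source_voxel[:, 2] == 3  # the flat face, away from grid sides
        face = pts.normals[inner & (pts.source_voxel[:, 0] > 1)
                           & (pts.source_voxel[:, 0] < 6)
                           & (pts.source_voxel[:, 1] > 1)
                           & (pts.source_voxel[:, 1] < 6)]
        assert len(face)
        np.testing.assert_allclose(face, np.tile([0, 0, 1.0], (len(face), 1)), atol=1e-6)

    def test_all_normals_unit_length(self, sphere_boundary):
        np.testing.assert_allclose(
            np.linalg.norm(sphere_boundary.normals, axis=1), 1.0, atol=1e-9
        )

    def test_sphere_normals_align_with_radial_direction(self, sphere_boundary, sphere_center):
        radial = sphere_boundary.points - sphere_center
        radial /= np.linalg.norm(radial, axis=1)[:, None]
        dots = np.einsum("ij,ij->i", sphere_boundary.normals, radial)
        angles = np.degrees(np.arccos(np.clip(dots, -1, 1)))
        assert angles.mean() < 10.0
        assert (dots > 0).mean() >= 0.99

    def test_corner_voxel_with_sigma_zero_gets_outward_normal(self):
        # asymmetric background neighborhood: the normal points toward
        # the +x,+y,+z background
        grid = np.zeros((3, 3, 3))
        grid[0, 0, 0] = 1
        vol = make_volume(grid)
        vox = np.array([[0, 0, 0]])
        pts = BoundaryPointSet(vol.world_coordinates(vox), np.zeros((1, 3)), vox)
        out = estimate_normals(vol, pts, sigma=0.0)
        np.testing.assert_allclose(np.linalg.norm(out.normals, axis=1), 1.0)
        assert (out.normals[0] > 0).all()

    def test_symmetric_isolated_voxel_with_sigma_zero_errors_naming_voxel(self):
        # all six background directions cancel: no orientation exists
        grid = np.zeros((3, 3, 3))
        grid[1, 1, 1] = 1
        vol = make_volume(grid)
        vox = np.array([[1, 1, 1]])
        pts = BoundaryPointSet(vol.world_coordinates(vox), np.zeros((1, 3)), vox)
        with pytest.raises(ValueError, match=r"\(1, 1, 1\)"):
            estimate_normals(vol, pts, sigma=0.0)

    def test_anisotropic_spacing_scales_gradient(self):
        # half-space in z with 1:1.3 spacing still gives pure-z normals
        grid = np.zeros((8, 8, 8))
        grid[:, :, :4] = 1
        pts = extract_boundary_points(make_volume(grid, spacing=(1, 1, 1.3)), sigma=1.0)
        center = (pts.source_voxel[:, :2] == 4).all(axis=1) & (pts.source_voxel[:, 2] == 3)
        np.testing.assert_allclose(pts.normals[center], [[0, 0, 1.0]], atol=1e-6)


class TestContours:
    def test_square_contour_scales_xy_and_slice(self):
        contours = [{"slice": 0, "pixels": [[2, 2], [6, 2], [6, 6], [2, 6]]}]
        pts, vol = contours_to_points(contours, spacing=(1, 1, 1.3), grid_shape=(9, 9, 3))
        assert len(pts) == 4
        np.testing.assert_allclose(pts.points[:, 2], 0.0)
        np.testing.assert_allclose(pts.points[0], [2, 2, 0])
        assert vol.grid[:, :, 0].sum() > 0

    def test_slice_z_coordinates_are_multiples_of_slice_spacing(self):
        contours = [
            {"slice": s, "pixels": [[2, 2], [6, 2], [6, 6], [2, 6]]} for s in range(4)
        ]
        pts, _ = contours_to_points(contours, spacing=(1, 1, 1.3), grid_shape=(9, 9, 6))
        zs = np.unique(np.round(pts.points[:, 2], 9))
        np.testing.assert_allclose(zs, [0.0, 1.3, 2.6, 3.9])

    def test_cylinder_stack_rasterization_matches_brute_force_boundary(self):
        theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        circle = np.column_stack([8 + 5 * np.cos(theta), 8 + 5 * np.sin(theta)])
        contours = [{"slice": s, "pixels": circle.tolist()} for s in range(1, 5)]
        pts, vol = contours_to_points(contours, spacing=(1, 1, 1), grid_shape=(17, 17, 7))
        boundary = extract_boundary_points(vol)
        expected = brute_force_boundary(vol.grid)
        assert len(boundary) == len(expected)

    def test_empty_contour_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            contours_to_points([], spacing=(1, 1, 1))

    def test_self_intersecting_contour_warns(self):
        bowtie = [{"slice": 0, "pixels": [[0, 0], [4, 4], [4, 0], [0, 4]]}]
        with pytest.warns(UserWarning, match="self-intersecting"):
            contours_to_points(bowtie, spacing=(1, 1, 1), grid_shape=(6, 6, 2))


def test_point_cloud_ply_export_round_trips(tmp_path, sphere_boundary):
    path = tmp_path / "cloud.ply"
    sphere_boundary.export_ply(path)
    text = path.read_text().splitlines()
    assert text[0] == "ply"
    n = int(next(l for l in text if l.startswith("element vertex")).split()[-1])
    assert n == len(sphere_boundary)
    first = np.array(text[text.index("end_header") + 1].split(), dtype=float)
    np.testing.assert_allclose(first[:3], sphere_boundary.points[0], rtol=1e-6)
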