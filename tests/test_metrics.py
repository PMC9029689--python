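import numpy as np
import pytest
import trimesh

from _oracles import brute_force_hausdorff, brute_force_point_mesh
from hybridsurf import (
    DistanceReport,
    absolute_distance,
    cumulative_distance_curve,
    export_colormap,
    hausdorff_distance,
    mean_curvature,
    point_mesh_distances,
)
from hybridsurf.mesh import TriangleMesh


def random_mesh(rng, n_vertices=30, n_faces=50):
    v = rng.normal(size=(n_vertices, 3)) * 3
    f = rng.integers(0, n_vertices, size=(n_faces, 3))
    f = f[(f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])]
    return TriangleMesh(v, f)


class TestAbsoluteDistance:
    def test_points_on_surface_have_zero_distance(self):
        mesh = TriangleMesh.from_trimesh(trimesh.creation.icosphere(1, radius=5.0))
        seg = mesh.centroids()[:20]  # centroids lie exactly on triangles
        d, rep = absolute_distance(seg, mesh)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)
        assert rep.max < 1e-12 and rep.min <= rep.mean <= rep.max
        assert rep.pct_below[0.5] == 100.0

    def test_cube_center_distance_is_half(self):
        box = TriangleMesh.from_trimesh(trimesh.creation.box(extents=(1, 1, 1)))
        d, _ = absolute_distance(np.array([[0.0, 0.0, 0.0]]), box)
        assert d[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_point_triangle_minimum(self, seed):
        rng = np.random.default_rng(seed)
        mesh = random_mesh(rng)
        pts = rng.normal(size=(40, 3)) * 4
        fast = point_mesh_distances(pts, mesh)
        brute = brute_force_point_mesh(pts, mesh.triangle_corners())
        np.testing.assert_allclose(fast, brute, atol=1e-9)

    def test_surface_distance_not_vertex_distance(self):
        # point above the center of a large triangle: vertex distance is
        # much larger than surface distance
        mesh = TriangleMesh(
            np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], dtype=float),
            np.array([[0, 1, 2]]),
        )
        d, _ = absolute_distance(np.array([[3.0, 3.0, 1.0]]), mesh)
        assert d[0] == pytest.approx(1.0)

    def test_empty_mesh_rejected(self):
        mesh = TriangleMesh(np.empty((0, 3)), np.empty((0, 3), dtype=int))
        with pytest.raises(ValueError):
            absolute_distance(np.array([[0.0, 0.0, 0.0]]), mesh)

    def test_fe_mesh_within_half_voxel_diagonal_of_its_mask(self, sphere_phantom, sphere_boundary):
        from hybridsurf import extract_from_mask

        _, vol, _ = sphere_phantom
        mesh = extract_from_mask(vol)
        d, _ = absolute_distance(sphere_boundary, mesh)
        assert d.max() <= np.sqrt(3) / 2 + 1e-9

    def test_statistics_scale_with_units(self, sphere_phantom, sphere_boundary):
        # voxel units vs mm with unit spacing: a pure scale factor
        from hybridsurf import extract_from_mask

        _, vol, _ = sphere_phantom
        mesh = extract_from_mask(vol)
        d_mm, rep_mm = absolute_distance(sphere_boundary, mesh)
        scale = 2.0
        scaled = TriangleMesh(mesh.vertices * scale, mesh.faces)
        d_sc, _ = absolute_distance(sphere_boundary.points * scale, scaled)
        np.testing.assert_allclose(d_sc, d_mm * scale, atol=1e-9)


class TestHausdorff:
    def test_identity_is_zero(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(50, 3))
        assert hausdorff_distance(A, A) == 0.0

    def test_single_pair_is_euclidean_distance(self):
        assert hausdorff_distance(np.array([[0, 0, 0]]), np.array([[3, 4, 0]])) == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(60, 3))
        B = rng.normal(size=(80, 3)) + 0.5
        assert hausdorff_distance(A, B) == pytest.approx(brute_force_hausdorff(A, B), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        A, B = rng.normal(size=(40, 3)), rng.normal(size=(30, 3))
        assert hausdorff_distance(A, B) == hausdorff_distance(B, A)

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            A, B, C = (rng.normal(size=(25, 3)) + rng.normal(size=3) for _ in range(3))
            assert hausdorff_distance(A, C) <= (
                hausdorff_distance(A, B) + hausdorff_distance(B, C) + 1e-12
            )

    def test_mesh_inputs_are_sampled(self):
        mesh = TriangleMesh.from_trimesh(trimesh.creation.icosphere(2, radius=5.0))
        h = hausdorff_distance(mesh, mesh.vertices)
        # any sampled surface point lies within one edge length of a vertex
        edges = mesh.edges()
        max_edge = np.linalg.norm(
            mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
        ).max()
        assert 0 < h < max_edge

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hausdorff_distance(np.empty((0, 3)), np.array([[0, 0, 0]]))


class TestCumulativeCurve:
    def test_all_zero_distances_reach_hundred_percent(self):
        curve = cumulative_distance_curve(np.zeros(10), [0.1, 0.5, 1.0])
        assert all(pct == 100.0 for _, pct in curve)

    def test_counting_example(self):
        curve = cumulative_distance_curve(np.array([0.2, 0.7, 1.5]), [0.5, 1.0])
        assert curve[0] == (0.5, pytest.approx(100 / 3))
        assert curve[1] == (1.0, pytest.approx(200 / 3))

    def test_monotone_non_decreasing(self):
        rng = np.random.default_rng(2)
        d = rng.exponential(size=500)
        curve = cumulative_distance_curve(d, np.linspace(0, 3, 20))
        pcts = [pct for _, pct in curve]
        assert all(b >= a for a, b in zip(pcts, pcts[1:]))

    def test_report_pct_below_monotone(self):
        rng = np.random.default_rng(3)
        rep = DistanceReport.from_distances(rng.exponential(size=300), thresholds=(0.25, 0.5, 1.0, 2.0))
        vals = [rep.pct_below[t] for t in sorted(rep.pct_below)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert 0 <= rep.min <= rep.mean <= rep.max


class TestMeanCurvature:
    def test_icosphere_median_matches_inverse_radius(self):
        mesh = TriangleMesh.from_trimesh(trimesh.creation.icosphere(4, radius=5.0))
        res = mean_curvature(mesh)
        med = np.median(res.values[res.valid])
        assert med == pytest.approx(0.2, rel=0.1)

    def test_flat_interior_vertices_have_zero_curvature(self):
        # regular triangulated grid in the plane z = 0
        n = 8
        xs, ys = np.meshgrid(np.arange(n), np.arange(n))
        v = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)]).astype(float)
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + 1, a + n])
                faces.append([a + 1, a + n + 1, a + n])
        mesh = TriangleMesh(v, np.array(faces))
        res = mean_curvature(mesh)
        interior = res.valid  # boundary vertices are skipped automatically
        assert interior.sum() == (n - 2) ** 2
        assert np.abs(res.values[interior]).max() < 1e-6

    def test_similarity_scaling_halves_curvature(self):
        mesh = TriangleMesh.from_trimesh(trimesh.creation.icosphere(3, radius=5.0))
        res1 = mean_curvature(mesh)
        res2 = mean_curvature(TriangleMesh(mesh.vertices * 2, mesh.faces))
        np.testing.assert_allclose(res2.values[res1.valid] * 2, res1.values[res1.valid], atol=1e-6)

    def test_histogram_percentages_sum_to_hundred(self):
        mesh = TriangleMesh.from_trimesh(trimesh.creation.icosphere(3, radius=5.0))
        res = mean_curvature(mesh)
        assert sum(p for _, _, p in res.histogram) == pytest.approx(100.0)


class TestColormap:
    def test_constant_values_give_single_color(self, tmp_path):
        mesh = TriangleMesh.from_trimesh(trimesh.creation.icosphere(1, radius=1.0))
        path = tmp_path / "c.ply"
        export_colormap(mesh, np.full(mesh.n_vertices, 3.0), path)
        back = trimesh.load(str(path), process=False)
        colors = np.asarray(back.visual.vertex_colors)
        assert (colors == colors[0]).all()

    def test_extreme_values_map_to_pure_blue_and_red(self, tmp_path):
        mesh = TriangleMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float),
            np.array([[0, 1, 2]]),
        )
        vals = np.array([0.0, 5.0, 2.5])
        path = tmp_path / "e.ply"
        export_colormap(mesh, vals, path)
        back = trimesh.load(str(path), process=False)
        colors = np.asarray(back.visual.vertex_colors)[:, :3]
        np.testing.assert_array_equal(colors[0], [0, 0, 255])   # blue = low
        np.testing.assert_array_equal(colors[1], [255, 0, 0])   # red = high
        np.testing.assert_array_equal(colors[2], [0, 255, 0])   # green = middle

    def test_round_trip_preserves_rgb_bytes(self, tmp_path):
        mesh = TriangleMesh.from_trimesh(trimesh.creation.icosphere(1, radius=1.0))
        vals = np.linspace(0, 1, mesh.n_vertices)
        p1, p2 = tmp_path / "a.ply", tmp_path / "b.ply"
        export_colormap(mesh, vals, p1)
        back = TriangleMesh.load(p1)
        back_colors = np.asarray(trimesh.load(str(p1), process=False).visual.vertex_colors)
        export_colormap(back, vals, p2)
        again = np.asarray(trimesh.load(str(p2), process=False).visual.vertex_colors)
        np.testing.assert_array_equal(back_colors, again)

    def test_length_mismatch_rejected(self):
        mesh = TriangleMesh.from_trimesh(trimesh.creation.icosphere(1, radius=1.0))
        with pytest.raises(ValueError, match="one value per vertex"):
            export_colormap(mesh, np.zeros(3), "/tmp/never.ply")
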