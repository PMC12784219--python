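"""Mesh and coordinate-geometry primitives."""

import numpy as np
import pytest

from pcawarp.mesh import (
    Fiducials,
    HeadModel,
    RigidTransform,
    SurfaceMesh,
    check_nesting,
    ctf_from_fiducials,
    cut_above_ears,
    decimate_pointcloud,
    move_inward,
    project_to_sphere_triangulation,
    ray_mesh_intersect,
    ray_mesh_intersect_many,
    star_ray_intersect,
    unit_sphere_mesh,
)


def brute_force_ray(mesh, origin, direction):
    """Independent per-triangle Moller-Trumbore loop (the oracle)."""
    origin = np.asarray(origin, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    best_t, best_tri = np.inf, -1
    for i, (a, b, c) in enumerate(zip(*mesh.triangle_corners())):
        e1, e2 = b - a, c - a
        p = np.cross(d, e2)
        det = e1 @ p
        if abs(det) < 1e-12:
            continue
        t_vec = origin - a
        u = (t_vec @ p) / det
        q = np.cross(t_vec, e1)
        v = (d @ q) / det
        t = (e2 @ q) / det
        if u >= -1e-9 and v >= -1e-9 and u + v <= 1 + 1e-9 and t > 1e-9 and t < best_t:
            best_t, best_tri = t, i
    return (best_t, best_tri) if best_tri >= 0 else (None, None)


class TestRayMeshIntersect:
    def test_unit_sphere_hit(self):
        m = unit_sphere_mesh(1922)
        hit = ray_mesh_intersect(m, [0, 0, 0], [1, 0, 0])
        assert hit is not None
        assert hit.distance == pytest.approx(1.0, abs=5e-3)  # chord tolerance
        assert np.allclose(hit.point, [1, 0, 0], atol=5e-3)

    def test_ray_pointing_away_misses(self):
        m = unit_sphere_mesh(162)
        assert ray_mesh_intersect(m, [10, 0, 0], [1, 0, 0]) is None

    def test_matches_brute_force_on_random_rays(self, bumpy_star_mesh):
        rng = np.random.default_rng(11)
        for _ in range(50):
            d = rng.standard_normal(3)
            o = rng.standard_normal(3) * 20.0
            hit = ray_mesh_intersect(bumpy_star_mesh, o, d)
            t_ref, tri_ref = brute_force_ray(bumpy_star_mesh, o, d)
            if t_ref is None:
                assert hit is None
            else:
                assert hit.distance == pytest.approx(t_ref, abs=1e-9)
                assert hit.triangle == tri_ref

    def test_star_shaped_single_hit_from_center(self, bumpy_star_mesh):
        rng = np.random.default_rng(3)
        dirs = rng.standard_normal((1000, 3))
        d, tri = ray_mesh_intersect_many(
            bumpy_star_mesh, np.zeros(3), dirs
        )
        assert np.all(np.isfinite(d))
        assert np.all(tri >= 0)

    def test_star_accelerated_equals_full_scan(self, bumpy_star_mesh):
        rng = np.random.default_rng(5)
        dirs = rng.standard_normal((300, 3))
        d_fast, t_fast = star_ray_intersect(bumpy_star_mesh, np.zeros(3), dirs)
        d_full, t_full = ray_mesh_intersect_many(bumpy_star_mesh, np.zeros(3), dirs)
        np.testing.assert_allclose(d_fast, d_full)
        np.testing.assert_array_equal(t_fast, t_full)

    def test_degenerate_triangles_skipped(self):
        verts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]])
        tris = np.array([[0, 1, 2], [0, 1, 3]])  # first is zero-area
        m = SurfaceMesh(verts, tris)
        hit = ray_mesh_intersect(m, [0.2, 0.2, 1.0], [0, 0, -1])
        assert hit is not None and hit.triangle == 1

    def test_zero_direction_raises(self, sphere162):
        with pytest.raises(ValueError):
            ray_mesh_intersect(sphere162, [0, 0, 0], [0, 0, 0])


class TestCtfFromFiducials:
    def test_already_ctf_gives_identity(self):
        fid = Fiducials([100, 0, 0], [0, 70, 0], [0, -70, 0])
        t = ctf_from_fiducials(fid)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(t.translation, 0, atol=1e-9)

    def test_postconditions_on_random_fiducials(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            fid = Fiducials(*rng.standard_normal((3, 3)) * 60)
            if fid.is_collinear():
                continue
            t = ctf_from_fiducials(fid)
            out = t.apply_fiducials(fid)
            assert np.allclose(0.5 * (out.lpa + out.rpa), 0, atol=1e-9)
            assert out.nas[0] > 0
            assert np.allclose(out.nas[1:], 0, atol=1e-9)
            assert abs(out.lpa[2]) < 1e-9 and abs(out.rpa[2]) < 1e-9
            assert out.lpa[1] > 0
            # distances preserved
            assert np.linalg.norm(out.nas - out.lpa) == pytest.approx(
                np.linalg.norm(fid.nas - fid.lpa)
            )

    def test_compose_and_invert_recovers_coordinates(self, bumpy_star_mesh):
        rng = np.random.default_rng(8)
        fid = Fiducials([95, 0, 0], [0, 72, 0], [0, -70, 0])
        # random proper rotation + translation
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        move = RigidTransform(q, rng.standard_normal(3) * 30)
        moved_fid = move.apply_fiducials(fid)
        moved_verts = move.apply(bumpy_star_mesh.vertices)
        back = ctf_from_fiducials(moved_fid)
        # original head was CTF-aligned iff ctf_from_fiducials(fid) is identity
        t0 = ctf_from_fiducials(fid)
        original = t0.apply(bumpy_star_mesh.vertices)
        recovered = back.apply(moved_verts)
        np.testing.assert_allclose(recovered, original, atol=1e-6)

    def test_collinear_raises(self):
        with pytest.raises(ValueError):
            ctf_from_fiducials(Fiducials([0, 0, 0], [1, 0, 0], [2, 0, 0]))


class TestProxyPreprocessing:
    FID = Fiducials([100, 0, 0], [0, 70, 0], [0, -70, 0])  # plane z = 0

    def test_cut_threshold(self):
        pts = np.array([[0, 0, 40.0], [0, 0, 30.0], [5, 5, 35.0]])
        kept = cut_above_ears(pts, self.FID, offset=35)
        assert len(kept) == 2  # 40 kept, 35 kept (ties kept), 30 dropped

    def test_cut_very_negative_offset_keeps_all(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((50, 3)) * 100
        assert len(cut_above_ears(pts, self.FID, offset=-1e9)) == 50

    def test_cut_matches_brute_force(self):
        rng = np.random.default_rng(1)
        fid = Fiducials(*rng.standard_normal((3, 3)) * 50)
        pts = rng.standard_normal((200, 3)) * 80
        kept = cut_above_ears(pts, fid, offset=10)
        # brute force: plane through the three fiducials, superior normal
        n = np.cross(fid.lpa - fid.nas, fid.rpa - fid.nas)
        n = n / np.linalg.norm(n)
        if (ctf_from_fiducials(fid).rotation @ n)[2] < 0:
            n = -n
        expected = pts[[(p - fid.nas) @ n >= 10 for p in pts]]
        np.testing.assert_allclose(kept, expected)

    def test_move_inward_sphere(self):
        rng = np.random.default_rng(4)
        u = rng.standard_normal((100, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        out = move_inward(100 * u, u, 12.0)
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 88.0, atol=1e-9)

    def test_move_inward_zero_distance_is_identity(self):
        pts = np.array([[1.0, 2, 3], [4, 5, 6]])
        n = np.array([[0, 0, 1.0], [0, 1.0, 0]])
        np.testing.assert_array_equal(move_inward(pts, n, 0.0), pts)

    def test_move_inward_ellipsoid_analytic(self):
        a, b, c = 100.0, 85.0, 90.0
        rng = np.random.default_rng(9)
        u = rng.standard_normal((50, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = 1.0 / np.sqrt((u[:, 0] / a) ** 2 + (u[:, 1] / b) ** 2 + (u[:, 2] / c) ** 2)
        pts = u * r[:, None]
        # analytic outward ellipsoid normal: grad(x^2/a^2 + ...) normalized
        grad = 2 * pts / np.array([a, b, c]) ** 2
        nrm = grad / np.linalg.norm(grad, axis=1, keepdims=True)
        got = move_inward(pts, 3.7 * grad, 5.0)  # non-unit normals get normalized
        np.testing.assert_allclose(got, pts - 5.0 * nrm, atol=1e-9)

    def test_move_inward_zero_normal_raises(self):
        with pytest.raises(ValueError):
            move_inward([[1.0, 0, 0]], [[0.0, 0, 0]], 1.0)


class TestProjectToSphereTriangulation:
    def test_constant_radius(self, sphere162):
        m = project_to_sphere_triangulation(
            lambda u: np.full(len(u), 100.0), np.zeros(3), sphere162
        )
        np.testing.assert_allclose(m.vertices, 100.0 * sphere162.vertices, atol=1e-12)
        np.testing.assert_array_equal(m.triangles, sphere162.triangles)
        assert m.star_center is not None

    def test_idempotent_on_own_radial_field(self, sphere162):
        def radial(u):
            return 90.0 + 7.0 * u[:, 2] ** 2

        m1 = project_to_sphere_triangulation(radial, np.zeros(3), sphere162)
        r1 = np.linalg.norm(m1.vertices, axis=1)

        def radial_of_m1(u):
            # same directions as reference vertices -> same radii
            return r1

        m2 = project_to_sphere_triangulation(radial_of_m1, np.zeros(3), sphere162)
        np.testing.assert_allclose(m2.vertices, m1.vertices, atol=1e-12)

    def test_ellipsoid_equation_satisfied(self, sphere162):
        a, b, c = 100.0, 85.0, 90.0

        def radial(u):
            return 1.0 / np.sqrt(
                (u[:, 0] / a) ** 2 + (u[:, 1] / b) ** 2 + (u[:, 2] / c) ** 2
            )

        m = project_to_sphere_triangulation(radial, np.zeros(3), sphere162)
        q = (m.vertices[:, 0] / a) ** 2 + (m.vertices[:, 1] / b) ** 2 + (
            m.vertices[:, 2] / c
        ) ** 2
        np.testing.assert_allclose(q, 1.0, atol=1e-9)

    def test_nonpositive_radius_raises(self, sphere162):
        with pytest.raises(ValueError):
            project_to_sphere_triangulation(
                lambda u: u[:, 2], np.zeros(3), sphere162
            )


def _nested_sphere_head(radii=(100.0, 95.0, 90.0, 85.0), v=162):
    ref = unit_sphere_mesh(v)
    tissues = ["scalp", "skull", "csf", "cortex"]
    shells = [
        SurfaceMesh(ref.vertices * r, ref.triangles, t, np.zeros(3))
        for r, t in zip(radii, tissues)
    ]
    fid = Fiducials([radii[0], 0, 0], [0, radii[0], 0], [0, -radii[0], 0])
    return HeadModel(shells, fid, "ctf")


class TestCheckNesting:
    def test_nested_spheres_ok(self):
        rep = check_nesting(_nested_sphere_head(), n_rays=100)
        assert rep.ok
        for gap in rep.min_gap_per_pair.values():
            assert gap == pytest.approx(5.0, abs=0.3)

    def test_swapped_shells_fail(self):
        head = _nested_sphere_head()
        shells = list(head.shells)
        # swap skull and csf geometry (keep tissue ordering of the container)
        shells[1], shells[2] = (
            shells[2].with_vertices(shells[2].vertices, tissue="skull"),
            shells[1].with_vertices(shells[1].vertices, tissue="csf"),
        )
        bad = HeadModel(shells, head.fiducials, "ctf")
        assert not check_nesting(bad, n_rays=50).ok

    def test_agrees_with_dense_raycasting(self, small_population):
        for head in small_population.heads[:4]:
            coarse = check_nesting(head, n_rays=50)
            dense = check_nesting(head, n_rays=500)
            assert coarse.ok == dense.ok


class TestDecimatePointcloud:
    def test_full_size_returns_input(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((30, 3))
        out = decimate_pointcloud(pts, 30)
        assert sorted(map(tuple, out)) == sorted(map(tuple, pts))

    def test_two_clusters(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.5, (500, 3))
        b = rng.normal(0, 0.5, (500, 3)) + [100, 0, 0]
        out = decimate_pointcloud(np.vstack([a, b]), 2)
        assert {p[0] < 50 for p in out} == {True, False}

    def test_spreads_better_than_random_subsets(self):
        rng = np.random.default_rng(2)
        u = rng.standard_normal((1000, 3))
        pts = 100 * u / np.linalg.norm(u, axis=1, keepdims=True)
        fps = decimate_pointcloud(pts, 150)

        def min_pairwise(p):
            d = np.linalg.norm(p[:, None] - p[None], axis=-1)
            return d[np.triu_indices(len(p), 1)].min()

        rand_scores = [
            min_pairwise(pts[np.random.default_rng(s).choice(1000, 150, replace=False)])
            for s in range(20)
        ]
        assert min_pairwise(fps) >= np.median(rand_scores)

    def test_invalid_target_raises(self):
        with pytest.raises(ValueError):
            decimate_pointcloud(np.zeros((10, 3)), 0)
        with pytest.raises(ValueError):
            decimate_pointcloud(np.zeros((10, 3)), 11)


class TestSurfaceMeshValidation:
    def test_rejects_bad_indices(self):
        with pytest.raises(ValueError):
            SurfaceMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))

    def test_rejects_repeated_vertex(self):
        with pytest.raises(ValueError):
            SurfaceMesh(np.zeros((3, 3)), np.array([[0, 1, 1]]))

    def test_headmodel_requires_shared_topology(self, sphere162):
        tissues = ["scalp", "skull", "csf", "cortex"]
        shells = [
            SurfaceMesh(sphere162.vertices * r, sphere162.triangles, t)
            for r, t in zip((100, 95, 90, 85), tissues)
        ]
        other = unit_sphere_mesh(42)
        shells[3] = SurfaceMesh(other.vertices * 85, other.triangles, "cortex")
        with pytest.raises(ValueError):
            HeadModel(shells, Fiducials([1, 0, 0], [0, 1, 0], [0, -1, 0]))
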