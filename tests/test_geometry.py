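"""Geometric primitives: reflection, rigid motion, volume, nearest point,
inside/outside classification and slab slicing."""

import numpy as np
import pytest
import trimesh

from torsofit._geometry import closest_point_on_triangles
from torsofit.mesh import (
    InvalidMeshError,
    Plane,
    RigidTransform,
    SurfaceMesh,
    apply_rigid,
    enclosed_volume,
    nearest_point_on_surface,
    nearest_points_on_surface,
    point_inside,
    reflect,
    slice_z,
)


def _rot_z(deg):
    a = np.deg2rad(deg)
    return np.array(
        [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
    )


class TestReflect:
    def test_involution(self, scoliotic_torso):
        plane = Plane([3.0, -2.0, 10.0], [0.3, 0.5, -0.8])
        back = reflect(reflect(scoliotic_torso, plane), plane)
        np.testing.assert_allclose(back.vertices, scoliotic_torso.vertices, atol=1e-9)

    def test_analytic_point_reflection(self):
        mesh = SurfaceMesh(np.array([[3.0, 1.0, 1.0], [0, 0, 0], [0, 1, 0], [1, 0, 0]]),
                           np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]]))
        r = reflect(mesh, Plane([1.0, 0.0, 0.0], [1.0, 0.0, 0.0]))
        np.testing.assert_allclose(r.vertices[0], [-1.0, 1.0, 1.0], atol=1e-12)

    def test_symmetric_cube_maps_to_itself(self, unit_cube):
        centered = SurfaceMesh(unit_cube.vertices - 0.5, unit_cube.faces)
        r = reflect(centered, Plane([0, 0, 0], [1, 0, 0]))
        a = sorted(map(tuple, np.round(centered.vertices, 9)))
        b = sorted(map(tuple, np.round(r.vertices, 9)))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_volume_sign_preserved(self, icosphere):
        m = icosphere(10.0)
        r = reflect(m, Plane([5.0, 1.0, 0.0], [0.6, 0.8, 0.0]))
        assert abs(enclosed_volume(r) - enclosed_volume(m)) < 1e-9 * enclosed_volume(m)


class TestRigid:
    def test_identity_and_inverse(self, scoliotic_torso):
        t = RigidTransform(_rot_z(37.0), [5.0, -3.0, 11.0])
        moved = apply_rigid(scoliotic_torso, t)
        back = apply_rigid(moved, t.inverse())
        np.testing.assert_allclose(back.vertices, scoliotic_torso.vertices, atol=1e-9)

    def test_analytic_rotation(self):
        t = RigidTransform(_rot_z(90.0), [0.0, 0.0, 0.0])
        np.testing.assert_allclose(t.apply([[1.0, 0.0, 0.0]])[0], [0, 1, 0], atol=1e-12)

    def test_pairwise_distances_preserved(self, unit_cube):
        t = RigidTransform(_rot_z(63.0), [4.0, 5.0, -6.0])
        moved = apply_rigid(unit_cube, t)
        d0 = np.linalg.norm(
            unit_cube.vertices[:, None] - unit_cube.vertices[None], axis=2
        )
        d1 = np.linalg.norm(moved.vertices[:, None] - moved.vertices[None], axis=2)
        np.testing.assert_allclose(d0, d1, rtol=1e-9)

    def test_volume_invariant(self, icosphere):
        m = icosphere(10.0)
        t = RigidTransform(_rot_z(20.0), [100.0, 0.0, -30.0])
        assert abs(enclosed_volume(apply_rigid(m, t)) - enclosed_volume(m)) < 1e-6

    def test_invalid_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), [0, 0, 0])  # reflection


class TestEnclosedVolume:
    def test_unit_cube(self, unit_cube):
        assert abs(enclosed_volume(unit_cube) - 1.0) < 1e-12

    def test_sphere_analytic(self, icosphere):
        m = icosphere(10.0, subdivisions=4)
        exact = 4.0 / 3.0 * np.pi * 1000.0
        assert abs(enclosed_volume(m) - exact) / exact < 0.005

    def test_inverted_winding(self, unit_cube):
        inv = SurfaceMesh(unit_cube.vertices, unit_cube.faces[:, ::-1])
        with pytest.raises(InvalidMeshError):
            enclosed_volume(inv)
        assert enclosed_volume(inv, allow_negative=True) == pytest.approx(-1.0)

    def test_open_mesh_reports_edges(self, unit_cube):
        open_mesh = SurfaceMesh(unit_cube.vertices, unit_cube.faces[:-1])
        with pytest.raises(InvalidMeshError, match="open"):
            enclosed_volume(open_mesh)


class TestNearestPoint:
    def test_vertex_query(self, icosphere):
        m = icosphere(10.0)
        p, d, fid = nearest_point_on_surface(m, m.vertices[17])
        assert d < 1e-12
        np.testing.assert_allclose(p, m.vertices[17], atol=1e-12)

    def test_above_square(self):
        m = SurfaceMesh(
            np.array([[-1, -1, 0], [1, -1, 0], [1, 1, 0], [-1, 1, 0.0]]),
            np.array([[0, 1, 2], [0, 2, 3]]),
        )
        p, d, _ = nearest_point_on_surface(m, [0.0, 0.0, 5.0])
        assert d == pytest.approx(5.0, abs=1e-12)
        np.testing.assert_allclose(p, [0, 0, 0], atol=1e-12)

    def test_matches_brute_force(self, icosphere):
        m = icosphere(20.0, subdivisions=2)  # 320 faces
        assert len(m.faces) <= 1000
        rng = np.random.default_rng(11)
        queries = rng.uniform(-30, 30, size=(100, 3))
        _, dists, _ = nearest_points_on_surface(m, queries)
        tri = m.vertices[m.faces]
        for q, d in zip(queries, dists):
            cand = closest_point_on_triangles(
                np.repeat(q[None, :], len(tri), axis=0), tri
            )
            brute = np.linalg.norm(cand - q, axis=1).min()
            assert abs(d - brute) < 1e-9


class TestPointInside:
    def test_cube_cases(self, unit_cube):
        assert point_inside(unit_cube, [0.5, 0.5, 0.5]) == "inside"
        assert point_inside(unit_cube, [5.0, 5.0, 5.0]) == "outside"
        assert point_inside(unit_cube, [0.0, 0.0, 0.0]) == "on-surface"

    def test_against_convex_halfspace_oracle(self, icosphere):
        m = icosphere(10.0, subdivisions=2)
        tri = m.vertices[m.faces]
        normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        offsets = np.einsum("ij,ij->i", normals, tri[:, 0])
        rng = np.random.default_rng(3)
        pts = rng.uniform(-12, 12, size=(1000, 3))
        margins = pts @ normals.T - offsets
        oracle_inside = (margins < -1e-6).all(axis=1)
        oracle_near = np.abs(margins).min(axis=1) < 1e-5
        for p, is_in, near in zip(pts, oracle_inside, oracle_near):
            if near:
                continue
            got = point_inside(m, p)
            assert got == ("inside" if is_in else "outside")

    def test_open_mesh_rejected(self, unit_cube):
        open_mesh = SurfaceMesh(unit_cube.vertices, unit_cube.faces[:-1])
        with pytest.raises(InvalidMeshError):
            point_inside(open_mesh, [0.5, 0.5, 0.5])


def _cylinder(radius=30.0, height=100.0, sections=128) -> SurfaceMesh:
    c = trimesh.creation.cylinder(radius=radius, height=height, sections=sections)
    c.apply_translation([0, 0, height / 2.0])
    return SurfaceMesh(c.vertices, c.faces)


class TestSliceZ:
    def test_half_cylinder_volume(self):
        cyl = _cylinder()
        whole = enclosed_volume(cyl)
        half = slice_z(cyl, 25.0, 75.0, cap=True)
        assert half.is_watertight
        assert abs(enclosed_volume(half) - whole / 2.0) < 1e-6 * whole

    def test_full_range_is_identity(self):
        cyl = _cylinder()
        out = slice_z(cyl, -1.0, 101.0, cap=True)
        assert len(out.faces) == len(cyl.faces)
        assert abs(enclosed_volume(out) - enclosed_volume(cyl)) < 1e-9

    def test_disjoint_interval_rejected(self):
        with pytest.raises(InvalidMeshError):
            slice_z(_cylinder(), 150.0, 200.0)

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            slice_z(_cylinder(), 75.0, 25.0)

    def test_open_shell_without_cap(self):
        shell = slice_z(_cylinder(), 25.0, 75.0, cap=False)
        assert not shell.is_watertight

    def test_volume_conservation_convex(self, icosphere):
        m = icosphere(50.0, subdivisions=3)
        whole = enclosed_volume(m)
        parts = [
            slice_z(m, -51.0, -15.0),
            slice_z(m, -15.0, 20.0),
            slice_z(m, 20.0, 51.0),
        ]
        total = sum(enclosed_volume(p) for p in parts)
        assert abs(total - whole) < 1e-6 * whole
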