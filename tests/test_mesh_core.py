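"""Mesh data model, differential operators and geometric measures."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from airwaysim.mesh import (
    DegenerateFaceError,
    OpenMeshError,
    TriangleMesh,
    centroids,
    cotangent_laplacian,
    enclosed_volume,
    face_areas,
    face_normals,
    load_mesh,
    one_ring_areas,
    save_mesh,
)

TRI = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


class TestFaceNormals:
    def test_right_hand_rule(self):
        m = TriangleMesh(TRI, [[0, 1, 2]])
        assert np.allclose(face_normals(m), [[0, 0, 1]])

    def test_reversed_winding_flips(self):
        m = TriangleMesh(TRI, [[0, 2, 1]])
        assert np.allclose(face_normals(m), [[0, 0, -1]])

    def test_icosphere_outward(self, icosphere):
        n = face_normals(icosphere)
        c = centroids(icosphere)
        assert (np.einsum("ij,ij->i", n, c) > 0).all()

    def test_unit_length(self, icosphere):
        n = face_normals(icosphere)
        assert np.abs(np.linalg.norm(n, axis=1) - 1).max() < 1e-9

    def test_degenerate_face_raises(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        with pytest.raises(DegenerateFaceError, match="0"):
            face_normals(TriangleMesh(v, [[0, 1, 2]]))

    def test_winding_preserving_permutation_invariant(self, icosphere):
        rolled = TriangleMesh(icosphere.vertices, np.roll(icosphere.faces, 1, axis=1))
        assert np.allclose(face_normals(icosphere), face_normals(rolled))


class TestCentroidsAndAreas:
    def test_centroid_is_mean(self):
        m = TriangleMesh(3 * TRI, [[0, 1, 2]])
        assert np.allclose(centroids(m), [[1, 1, 0]])

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-10, 10), min_size=9, max_size=9))
    def test_random_triangle_centroid(self, coords):
        v = np.array(coords).reshape(3, 3)
        m = TriangleMesh(v, [[0, 1, 2]])
        assert np.allclose(centroids(m)[0], v.mean(axis=0))

    def test_right_triangle_area(self):
        m = TriangleMesh(TRI, [[0, 1, 2]])
        assert np.isclose(face_areas(m)[0], 0.5)

    def test_cube_total_area(self, cube):
        assert np.isclose(face_areas(cube).sum(), 6.0)

    def test_one_ring_matches_incidence_enumeration(self, cube):
        fa = face_areas(cube)
        expected = np.zeros(cube.n_vertices)
        for fi, f in enumerate(cube.faces):
            for v in f:
                expected[v] += fa[fi]
        assert np.allclose(one_ring_areas(cube), expected)


class TestCotangentLaplacian:
    def test_equilateral_pair_weight(self):
        h = np.sqrt(3) / 2
        v = np.array([[0, 0, 0], [1, 0, 0], [0.5, h, 0], [0.5, -h, 0.0]])
        L = cotangent_laplacian(TriangleMesh(v, [[0, 1, 2], [0, 3, 1]]))
        assert np.isclose(L[0, 1], 2 / np.sqrt(3), atol=1e-12)
        assert np.isclose(L[0, 1], 1.1547, atol=1e-4)

    def test_square_edge_weights(self):
        # unit square split along its diagonal into two right isoceles
        # triangles: the diagonal faces the two 90-degree corners
        # (cot 90 + cot 90 = 0) and each boundary side faces a single
        # 45-degree corner (cot 45 = 1)
        v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.0]])
        L = cotangent_laplacian(TriangleMesh(v, [[0, 1, 2], [0, 2, 3]]))
        assert np.isclose(L[0, 2], 0.0, atol=1e-12)
        assert np.isclose(L[0, 1], 1.0)
        assert np.isclose(L[0, 3], 1.0)

    def test_annihilates_constants(self, icosphere):
        L = cotangent_laplacian(icosphere)
        assert np.abs(L @ np.ones(icosphere.n_vertices)).max() < 1e-10

    def test_row_sums_vanish(self, unit_cylinder):
        L = cotangent_laplacian(unit_cylinder)
        rs = np.abs(np.asarray(L.sum(axis=1))).max()
        assert rs <= 1e-8 * np.abs(L.data).max()

    def test_structurally_symmetric(self, icosphere):
        L = cotangent_laplacian(icosphere)
        assert (abs(L - L.T) > 1e-12).nnz == 0

    def test_near_degenerate_clamped_with_warning(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0.5, 1e-12, 0], [0.5, -1, 0.0]])
        with pytest.warns(RuntimeWarning, match="clamped"):
            L = cotangent_laplacian(TriangleMesh(v, [[0, 1, 2], [0, 3, 1]]))
        assert np.abs(L.data).max() <= 4e8


class TestEnclosedVolume:
    def test_unit_cube(self, cube):
        assert np.isclose(enclosed_volume(cube), 1.0)

    def test_icosphere_analytic(self):
        ic = trimesh.creation.icosphere(subdivisions=4)
        m = TriangleMesh(np.array(ic.vertices), np.array(ic.faces))
        assert abs(enclosed_volume(m) - 4 / 3 * np.pi) < 0.01 * 4 / 3 * np.pi

    def test_flipped_orientation_negates(self, cube):
        flipped = TriangleMesh(cube.vertices, cube.faces[:, ::-1])
        assert np.isclose(enclosed_volume(flipped), -enclosed_volume(cube))

    def test_open_mesh_raises_with_count(self):
        m = TriangleMesh(TRI, [[0, 1, 2]])
        with pytest.raises(OpenMeshError, match="3 boundary"):
            enclosed_volume(m)

    @settings(deadline=None, max_examples=15)
    @given(st.lists(st.floats(0.2, 3.0), min_size=3, max_size=3))
    def test_affine_scaling_by_determinant(self, small_icosphere, diag):
        A = np.diag(diag)
        scaled = small_icosphere.with_vertices(small_icosphere.vertices @ A.T)
        v0 = enclosed_volume(small_icosphere)
        assert np.isclose(enclosed_volume(scaled), np.linalg.det(A) * v0,
                          rtol=1e-9)

    def test_agrees_with_trimesh(self, unit_cylinder):
        tm = unit_cylinder.to_trimesh()
        assert np.isclose(enclosed_volume(unit_cylinder), tm.volume, rtol=1e-9)


class TestIO:
    @pytest.mark.parametrize("ext", ["obj", "stl", "ply", "off"])
    def test_round_trip(self, tmp_path, small_icosphere, ext):
        p = tmp_path / f"m.{ext}"
        save_mesh(small_icosphere, p)
        back = load_mesh(p)
        assert back.n_faces == small_icosphere.n_faces
        assert np.isclose(
            enclosed_volume(back), enclosed_volume(small_icosphere), rtol=1e-5
        )

    def test_face_index_validation(self):
        with pytest.raises(ValueError):
            TriangleMesh(TRI, [[0, 1, 5]])
        with pytest.raises(ValueError):
            TriangleMesh(TRI, [[0, 1, 1]])
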