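"""Bilateral normal filtering, normal-driven vertex update, Taubin."""

import numpy as np
import pytest
import trimesh

from airwaysim.mesh import TriangleMesh, enclosed_volume, face_normals
from airwaysim.smoothing import (
    BilateralParams,
    bilateral_normal_filter,
    taubin_smooth,
    vertex_update_from_normals,
)
from conftest import make_plane


@pytest.fixture(scope="module")
def noisy_sphere():
    ic = trimesh.creation.icosphere(subdivisions=3)
    clean = TriangleMesh(np.array(ic.vertices), np.array(ic.faces))
    rng = np.random.default_rng(0)
    noisy = clean.with_vertices(
        clean.vertices + 0.01 * rng.standard_normal(clean.vertices.shape)
    )
    return clean, noisy


class TestBilateralFilter:
    def test_plane_normals_unchanged(self, plane):
        out = bilateral_normal_filter(plane)
        assert np.allclose(out, face_normals(plane), atol=1e-12)

    def test_output_unit_length(self, noisy_sphere):
        _clean, noisy = noisy_sphere
        out = bilateral_normal_filter(noisy)
        assert np.abs(np.linalg.norm(out, axis=1) - 1).max() < 1e-9

    def test_denoises_normals(self, noisy_sphere):
        clean, noisy = noisy_sphere
        n_clean = face_normals(clean)

        def ang_err(n):
            return np.degrees(
                np.arccos(np.clip(np.einsum("ij,ij->i", n, n_clean), -1, 1))
            ).mean()

        out = bilateral_normal_filter(noisy)
        assert ang_err(out) < ang_err(face_normals(noisy))

    def test_permutation_equivariant(self, noisy_sphere):
        _clean, noisy = noisy_sphere
        rng = np.random.default_rng(4)
        perm = rng.permutation(noisy.n_faces)
        permuted = TriangleMesh(noisy.vertices, noisy.faces[perm])
        a = bilateral_normal_filter(noisy)
        b = bilateral_normal_filter(permuted)
        assert np.allclose(a[perm], b, atol=1e-9)

    def test_parameter_validation(self):
        for kw in (dict(sigma_m=-1.0), dict(sigma_n=0.0), dict(zeta=0),
                   dict(k_nn=2)):
            with pytest.raises(ValueError):
                BilateralParams(**kw)


class TestVertexUpdate:
    def test_plane_is_fixed_point(self, plane):
        out = vertex_update_from_normals(plane, face_normals(plane), 3)
        assert np.abs(out.vertices - plane.vertices).max() < 1e-12

    def test_displacement_contracts(self, plane):
        v = plane.vertices.copy()
        bump = 27  # interior vertex
        v[bump, 2] = 0.5
        bumped = plane.with_vertices(v)
        normals = face_normals(plane)  # target: the flat plane
        prev = 0.5
        cur = bumped
        for _ in range(3):
            cur = vertex_update_from_normals(cur, normals, 1)
            assert abs(cur.vertices[bump, 2]) < prev
            prev = abs(cur.vertices[bump, 2])

    def test_iterations_compose(self, noisy_sphere):
        _clean, noisy = noisy_sphere
        normals = bilateral_normal_filter(noisy)
        three = vertex_update_from_normals(noisy, normals, 3)
        stepped = noisy
        for _ in range(3):
            stepped = vertex_update_from_normals(stepped, normals, 1)
        assert np.allclose(three.vertices, stepped.vertices, atol=1e-12)


class TestTaubin:
    def test_plane_unchanged(self, plane):
        out = taubin_smooth(plane, 0.33, -0.34, 10)
        # interior stays planar; boundary may drift within the plane
        assert np.abs(out.vertices[:, 2]).max() < 1e-12

    def test_passband_preserves_volume(self, icosphere):
        sm = taubin_smooth(icosphere, 0.33, -0.34, 10)
        v0 = enclosed_volume(icosphere)
        assert abs(enclosed_volume(sm) - v0) < 0.02 * v0
        # plain Laplacian (mu = 0 equivalent: lambda steps only) shrinks more
        shrunk = icosphere.copy()
        for _ in range(10):
            shrunk = taubin_smooth(shrunk, 0.33, -1e-9 - 0.33, 1)
        assert enclosed_volume(shrunk) < enclosed_volume(sm)

    def test_anchors_fixed(self, icosphere):
        anchors = np.arange(0, icosphere.n_vertices, 7)
        out = taubin_smooth(icosphere, 0.33, -0.34, 10, anchors=anchors)
        assert np.array_equal(out.vertices[anchors], icosphere.vertices[anchors])

    def test_invalid_steps_rejected(self, plane):
        with pytest.raises(ValueError):
            taubin_smooth(plane, 0.5, -0.4, 1)


def test_boundary_seam_dihedral_reduced(branch_pair):
    """Narrowing then smoothing lowers the worst seam crease angle."""
    from airwaysim.bronchoconstriction import NarrowingSpec, \
        simulate_bronchoconstriction

    mesh, labels, _tree = branch_pair
    region = np.flatnonzero(labels.region == "gen1")
    res = simulate_bronchoconstriction(
        mesh, NarrowingSpec(r=0.7, e=0.05, t=4, omega=0.8, region=region)
    )
    vids = np.unique(mesh.faces[region])
    boundary_faces = np.flatnonzero(
        np.isin(mesh.faces, vids).any(axis=1)
        != np.isin(mesh.faces, vids).all(axis=1)
    )

    def worst_crease(m):
        n = face_normals(m)
        adj = m.face_adjacency()
        seam = adj[np.isin(adj, boundary_faces).any(axis=1)]
        cosang = np.einsum("ij,ij->i", n[seam[:, 0]], n[seam[:, 1]])
        return np.degrees(np.arccos(np.clip(cosang, -1, 1))).max()

    anchors = np.flatnonzero(~np.isin(np.arange(mesh.n_vertices), vids))
    smoothed = taubin_smooth(res.mesh, 0.33, -0.34, 10, anchors=anchors)
    assert worst_crease(smoothed) < worst_crease(res.mesh)
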