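"""Ratio-targeted narrowing, geodesic distances, abnormality weighting."""

import numpy as np
import pytest

from airwaysim.bronchoconstriction import (
    NarrowingSpec,
    abnormality_weights,
    geodesic_distance,
    simulate_bronchoconstriction,
)
from airwaysim.mesh import TriangleMesh, centroids


@pytest.fixture(scope="module")
def narrowed(branch_pair):
    mesh, labels, _tree = branch_pair
    region = np.flatnonzero(labels.region == "gen1")
    spec = NarrowingSpec(r=0.5, e=0.05, t=8, omega=0.8, region=region)
    return mesh, region, simulate_bronchoconstriction(mesh, spec)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw",
        [dict(r=0.0), dict(r=1.0), dict(e=-0.1), dict(r=0.97, e=0.05),
         dict(t=0), dict(omega=1.2)],
    )
    def test_invalid_parameters(self, kw):
        with pytest.raises(ValueError):
            NarrowingSpec(**kw)

    def test_missing_region(self, small_icosphere):
        with pytest.raises(ValueError, match="region"):
            simulate_bronchoconstriction(small_icosphere, NarrowingSpec())


class TestNarrowing:
    def test_reaches_target_band(self, narrowed):
        _mesh, _region, res = narrowed
        assert res.converged
        assert res.achieved_ratio <= 0.55
        assert res.achieved_ratio >= 0.40

    def test_ratio_log_strictly_decreasing(self, narrowed):
        _mesh, _region, res = narrowed
        ratios = [r for _i, r, _v in res.log]
        assert all(b < a for a, b in zip(ratios, ratios[1:]))

    def test_outside_region_anchored(self, narrowed):
        mesh, region, res = narrowed
        moved = np.linalg.norm(res.mesh.vertices - mesh.vertices, axis=1)
        vids = np.unique(mesh.faces[region])
        outside = np.ones(mesh.n_vertices, bool)
        outside[vids] = False
        bbox = np.linalg.norm(mesh.vertices.max(0) - mesh.vertices.min(0))
        assert moved[outside].max() <= 1e-9 * bbox

    def test_watertight_preserved(self, narrowed):
        _mesh, _region, res = narrowed
        assert res.mesh.is_watertight

    def test_loose_target_terminates_immediately(self, unit_cylinder):
        c = centroids(unit_cylinder)
        region = np.flatnonzero((c[:, 2] > 3) & (c[:, 2] < 7))
        spec = NarrowingSpec(r=0.89, e=0.1, t=8, omega=0.8, region=region)
        res = simulate_bronchoconstriction(unit_cylinder, spec)
        assert res.converged
        assert res.iterations <= 2

    def test_scale_equivariance(self, unit_cylinder):
        """Meters vs millimeters: identical narrowing, scaled geometry."""
        c = centroids(unit_cylinder)
        region = np.flatnonzero((c[:, 2] > 3) & (c[:, 2] < 7))
        spec = NarrowingSpec(r=0.6, e=0.05, t=4, omega=0.8, region=region)
        res1 = simulate_bronchoconstriction(unit_cylinder, spec)
        # power-of-two scale: the unit-area normalization is then exact in
        # floating point and the whole run is bit-reproducible
        big = unit_cylinder.with_vertices(unit_cylinder.vertices * 1024.0)
        res2 = simulate_bronchoconstriction(big, spec)
        assert res2.achieved_ratio == pytest.approx(res1.achieved_ratio, abs=1e-9)
        assert np.allclose(res2.mesh.vertices, 1024.0 * res1.mesh.vertices,
                           rtol=1e-9, atol=1e-12)


class TestGeodesic:
    def test_zero_at_anchor(self, small_icosphere):
        d = geodesic_distance(small_icosphere, [5])
        assert d[5] == 0.0
        assert (d[np.arange(len(d)) != 5] > 0).all()

    def test_unit_path_graph(self):
        n = 6
        v = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
        v = np.vstack([v, [[i + 0.5, 1.0, 0.0] for i in range(n - 1)]])
        faces = [[i, i + 1, n + i] for i in range(n - 1)]
        mesh = TriangleMesh(v, np.array(faces))
        d = geodesic_distance(mesh, [0])
        assert np.allclose(d[:n], np.arange(n))

    def test_matches_networkx_oracle(self, unit_cylinder):
        import networkx as nx

        anchors = [0, 7]
        d = geodesic_distance(unit_cylinder, anchors)
        g = nx.Graph()
        e = unit_cylinder.edges_unique
        w = np.linalg.norm(
            unit_cylinder.vertices[e[:, 0]] - unit_cylinder.vertices[e[:, 1]],
            axis=1,
        )
        g.add_weighted_edges_from(zip(e[:, 0].tolist(), e[:, 1].tolist(), w))
        ref = nx.multi_source_dijkstra_path_length(g, anchors)
        ref_arr = np.array([ref[i] for i in range(unit_cylinder.n_vertices)])
        assert np.allclose(d, ref_arr)

    def test_empty_anchor_set_rejected(self, small_icosphere):
        with pytest.raises(ValueError):
            geodesic_distance(small_icosphere, [])


class TestAbnormality:
    def test_zero_distance_gives_omega(self):
        w = abnormality_weights(np.zeros(5), omega=0.8)
        assert np.allclose(w.W_V, 0.8)

    def test_peak_value(self):
        d = np.array([np.pi / 2])  # sin d = 1 at wavenumber 1
        w = abnormality_weights(d, omega=0.8)
        assert np.isclose(w.W_V[0], 0.9)

    def test_omega_one_no_modulation(self):
        w = abnormality_weights(np.linspace(0, 10, 20), omega=1.0)
        assert np.allclose(w.W_V, 1.0)

    def test_bounds_of_sinusoid(self):
        d = np.linspace(0, 20, 500)
        w = abnormality_weights(d, omega=0.8)
        assert w.W_V.min() >= 0.8 - 0.1 - 1e-12
        assert w.W_V.max() <= 0.8 + 0.1 + 1e-12

    def test_custom_function(self):
        w = abnormality_weights(np.array([1.0, 2.0]), omega=0.5,
                                fn=lambda d: 0.3 * np.ones_like(d))
        assert np.allclose(w.W_V, 0.3)

    def test_modulated_narrowing_is_nonuniform(self, unit_cylinder):
        """With the sinusoidal profile, radial displacement varies axially."""
        c = centroids(unit_cylinder)
        region = np.flatnonzero((c[:, 2] > 2) & (c[:, 2] < 8))
        spec = NarrowingSpec(r=0.7, e=0.05, t=4, omega=0.8, region=region,
                             abnormality=True, wavenumber=2 * np.pi / 3.0)
        res = simulate_bronchoconstriction(unit_cylinder, spec)
        r_orig = np.hypot(*unit_cylinder.vertices[:, :2].T)
        r_new = np.hypot(*res.mesh.vertices[:, :2].T)
        vids = np.unique(unit_cylinder.faces[region])
        core = vids[(unit_cylinder.vertices[vids, 2] > 3.5)
                    & (unit_cylinder.vertices[vids, 2] < 6.5)]
        disp = r_orig[core] - r_new[core]
        # displacement spread along the tube well above radial noise
        assert disp.max() - disp.min() > 0.2 * disp.max()
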