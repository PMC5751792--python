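"""Shared fixtures: small analytic meshes and synthetic airway geometries.

Everything is generated programmatically; session scope keeps the heavier
marching-cubes trees and contraction runs shared across test modules.
"""

import numpy as np
import pytest
import trimesh

from airwaysim.mesh import TriangleMesh
from airwaysim.synthetic import TreeSpec, generate_cylinder, generate_tree


@pytest.fixture(scope="session")
def icosphere():
    ic = trimesh.creation.icosphere(subdivisions=3)
    return TriangleMesh(np.array(ic.vertices), np.array(ic.faces))


@pytest.fixture(scope="session")
def small_icosphere():
    ic = trimesh.creation.icosphere(subdivisions=1)  # 42 vertices
    return TriangleMesh(np.array(ic.vertices), np.array(ic.faces))


@pytest.fixture(scope="session")
def unit_cylinder():
    """Radius 1, length 10, watertight."""
    return generate_cylinder(1.0, 10.0)


@pytest.fixture(scope="session")
def cube():
    c = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriangleMesh(np.array(c.vertices), np.array(c.faces))


@pytest.fixture(scope="session")
def branch_pair():
    """Trachea + two ~2 mm-radius child tubes: the narrowing fixture."""
    mesh, labels, tree = generate_tree(TreeSpec(generations=1, root_diameter=0.005))
    return mesh, labels, tree


@pytest.fixture(scope="session")
def tree2():
    """Two bifurcation levels, coarse, for contraction/skeleton runs."""
    mesh, labels, tree = generate_tree(
        TreeSpec(generations=2, root_diameter=0.008, mesh_resolution=0.0008)
    )
    return mesh, labels, tree


@pytest.fixture(scope="session")
def tree5():
    """Full 5-generation tree for transport runs."""
    mesh, labels, tree = generate_tree(TreeSpec(generations=5))
    return mesh, labels, tree


def make_plane(nx=8, ny=8):
    xs, ys = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    pts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)])
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            b = a + 1
            c = a + nx
            d = c + 1
            faces += [[a, b, d], [a, d, c]]
    return TriangleMesh(pts, np.array(faces))


@pytest.fixture()
def plane():
    return make_plane()
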