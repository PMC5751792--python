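"""Triangle-mesh data model and differential-geometry operators.

The mesh is the substrate of the whole pipeline: every geometric stage
(contraction, skeletonization, shape-diameter analysis, smoothing, particle
walls) operates on a :class:`TriangleMesh`.  Vertices are stored in meters.

The cotangent (curvature-flow) Laplacian built here is the operator that
drives the constrained contraction solve: its off-diagonal entry on an edge
``(i, j)`` is ``cot(a_ij) + cot(b_ij)`` where ``a_ij`` and ``b_ij`` are the
two angles facing the edge in its adjacent triangles, and the diagonal is
minus the row sum, so the matrix annihilates constant vector fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import trimesh as _trimesh

__all__ = [
    "TriangleMesh",
    "DegenerateFaceError",
    "OpenMeshError",
    "face_normals",
    "centroids",
    "face_areas",
    "one_ring_areas",
    "cotangent_laplacian",
    "enclosed_volume",
    "load_mesh",
    "save_mesh",
]

#: cot(angle) is clamped to this cap; contraction drives triangles toward
#: degeneracy and unbounded weights destroy the least-squares solve.
COT_CAP = 1.0e8


class DegenerateFaceError(ValueError):
    """A face has (numerically) zero area where a finite one is required."""


class OpenMeshError(ValueError):
    """The mesh has boundary edges where a closed surface is required."""


@dataclass
class TriangleMesh:
    """Indexed triangle surface: ``vertices`` (n, 3) float, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray
    _edge_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face indices out of range")
            if (np.diff(np.sort(self.faces, axis=1), axis=1) == 0).any():
                raise ValueError("faces with repeated vertices are not allowed")

    # -- basic counts ------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same connectivity, new vertex positions (shares the face array)."""
        m = TriangleMesh(np.asarray(vertices, float), self.faces)
        return m

    # -- connectivity ------------------------------------------------------
    @property
    def edges_unique(self) -> np.ndarray:
        """(e, 2) sorted unique undirected edges."""
        if "edges" not in self._edge_cache:
            e = np.sort(
                self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
            )
            self._edge_cache["edges"], self._edge_cache["edge_counts"] = np.unique(
                e, axis=0, return_counts=True
            )
        return self._edge_cache["edges"]

    @property
    def boundary_edge_count(self) -> int:
        self.edges_unique
        return int((self._edge_cache["edge_counts"] == 1).sum())

    @property
    def is_watertight(self) -> bool:
        self.edges_unique
        return bool((self._edge_cache["edge_counts"] == 2).all())

    def face_adjacency(self) -> np.ndarray:
        """(p, 2) pairs of face indices sharing an edge."""
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        face_idx = np.repeat(np.arange(self.n_faces), 3)
        order = np.lexsort((e[:, 1], e[:, 0]))
        e, face_idx = e[order], face_idx[order]
        same = (np.diff(e, axis=0) == 0).all(axis=1)
        return np.column_stack([face_idx[:-1][same], face_idx[1:][same]])

    def vertex_face_incidence(self) -> sp.csr_matrix:
        """Sparse (n_vertices, n_faces) 0/1 incidence matrix."""
        rows = self.faces.ravel()
        cols = np.repeat(np.arange(self.n_faces), 3)
        data = np.ones(len(rows))
        mat = sp.coo_matrix(
            (data, (rows, cols)), shape=(self.n_vertices, self.n_faces)
        ).tocsr()
        mat.data[:] = 1.0  # collapse duplicates from degenerate input
        return mat

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


# ---------------------------------------------------------------------------
# geometric measures
# ---------------------------------------------------------------------------

def _cross_products(mesh: TriangleMesh) -> np.ndarray:
    v = mesh.vertices[mesh.faces]
    return np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])


def face_normals(mesh: TriangleMesh) -> np.ndarray:
    """Outward unit normals, one per face, by the right-hand winding rule."""
    cross = _cross_products(mesh)
    norms = np.linalg.norm(cross, axis=1)
    bad = norms < 1e-300
    if bad.any():
        raise DegenerateFaceError(
            f"zero-area faces at indices {np.flatnonzero(bad).tolist()}"
        )
    return cross / norms[:, None]


def centroids(mesh: TriangleMesh) -> np.ndarray:
    """Arithmetic mean of each face's three vertices."""
    return mesh.vertices[mesh.faces].mean(axis=1)


def face_areas(mesh: TriangleMesh) -> np.ndarray:
    return 0.5 * np.linalg.norm(_cross_products(mesh), axis=1)


def one_ring_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex sum of the areas of the incident faces."""
    fa = face_areas(mesh)
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, mesh.faces.ravel(), np.repeat(fa, 3))
    return out


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Signed volume by the divergence theorem; positive for outward winding."""
    if not mesh.is_watertight:
        raise OpenMeshError(
            f"mesh is not closed: {mesh.boundary_edge_count} boundary edges"
        )
    v = mesh.vertices[mesh.faces]
    return float(np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0)


# ---------------------------------------------------------------------------
# cotangent Laplacian
# ---------------------------------------------------------------------------

def cotangent_laplacian(
    mesh: TriangleMesh, cot_cap: float = COT_CAP
) -> sp.csr_matrix:
    """Curvature-flow Laplacian with edge weights ``cot a_ij + cot b_ij``.

    Boundary edges (non-watertight input) contribute their single available
    angle.  Cotangents of near-degenerate angles are clamped to ``cot_cap``
    in magnitude; a warning is emitted when clamping occurs.
    """
    f = mesh.faces
    v = mesh.vertices
    n = mesh.n_vertices

    ii, jj, ww = [], [], []
    # for each corner k of each face, the cotangent at k weights the
    # opposite edge (k+1, k+2)
    for k in range(3):
        o = f[:, k]
        a = f[:, (k + 1) % 3]
        b = f[:, (k + 2) % 3]
        u = v[a] - v[o]
        w = v[b] - v[o]
        cot = np.einsum("ij,ij->i", u, w) / np.maximum(
            np.linalg.norm(np.cross(u, w), axis=1), 1e-300
        )
        ii.append(a)
        jj.append(b)
        ww.append(cot)
    cot_all = np.concatenate(ww)
    if (np.abs(cot_all) > cot_cap).any():
        warnings.warn(
            "near-degenerate triangles: cotangent weights clamped",
            RuntimeWarning,
            stacklevel=2,
        )
        cot_all = np.clip(cot_all, -cot_cap, cot_cap)
    rows = np.concatenate(ii)
    cols = np.concatenate(jj)
    W = sp.coo_matrix(
        (cot_all, (rows, cols)), shape=(n, n)
    )
    W = (W + W.T).tocsr()  # symmetrize: each edge gets both adjacent angles
    d = np.asarray(W.sum(axis=1)).ravel()
    L = W - sp.diags(d)
    return L.tocsr()


# ---------------------------------------------------------------------------
# file I/O (delegated to trimesh; 0-based indexing internally)
# ---------------------------------------------------------------------------

def load_mesh(path) -> TriangleMesh:
    """Read OBJ/STL/PLY/OFF; faces are triangulated on load."""
    tm = _trimesh.load(str(path), force="mesh", process=False)
    tm.merge_vertices()  # STL stores one vertex triple per facet
    faces = np.asarray(tm.faces)
    if faces.shape[1] != 3:  # pragma: no cover - trimesh triangulates
        tm = tm.triangulate()
        faces = np.asarray(tm.faces)
    return TriangleMesh(np.asarray(tm.vertices, float), faces)


def save_mesh(mesh: TriangleMesh, path) -> None:
    mesh.to_trimesh().export(str(path))
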