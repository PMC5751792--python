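"""Edge-effect mitigation where a deformed region rejoins the intact mesh.

Two complementary tools:

* **Bilateral normal filtering with vertex update** — face normals are
  averaged through a row-stochastic operator built from Gaussian weights on
  centroid distance and normal difference over a k-nearest-neighbor
  adjacency, then vertices are moved to agree with the filtered normals.
  Feature-preserving: large normal jumps (creases) damp the averaging.
* **Taubin smoothing** — alternating positive/negative uniform-Laplacian
  steps (a pass-band filter that smooths without the volume shrinkage of
  plain Laplacian smoothing), with optional hard anchor vertices at the
  boundary of the stable area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .mesh import TriangleMesh, centroids, face_normals

__all__ = [
    "BilateralParams",
    "bilateral_normal_filter",
    "vertex_update_from_normals",
    "taubin_smooth",
]


@dataclass
class BilateralParams:
    """Bandwidths and neighborhood size of the bilateral normal filter.

    ``sigma_m`` (mesh units) defaults to the mean centroid–neighbor
    distance; ``sigma_n`` acts on Euclidean differences of unit normals.
    """

    sigma_m: float | None = None
    sigma_n: float = 0.35
    zeta: int = 1
    k_nn: int = 8
    iterations: int = 5

    def __post_init__(self):
        if self.sigma_m is not None and self.sigma_m <= 0:
            raise ValueError("sigma_m must be positive")
        if self.sigma_n <= 0:
            raise ValueError("sigma_n must be positive")
        if self.zeta < 1:
            raise ValueError("zeta must be a positive integer")
        if self.k_nn < 3:
            raise ValueError("k_nn must be >= 3")


def bilateral_normal_filter(
    mesh: TriangleMesh, params: BilateralParams | None = None
) -> np.ndarray:
    """Filtered per-face unit normals ``(D^-1 C_w)^zeta n``.

    ``C_w = W_m W_n C_a`` where ``C_a`` is the k-nearest-neighbor binary
    adjacency of face centroids, ``W_m``/``W_n`` Gaussian weights on
    centroid distance and normal difference, and ``D`` the row-sum
    normalizer that makes the operator an averaging filter.
    """
    params = params or BilateralParams()
    cents = centroids(mesh)
    normals = face_normals(mesh)
    m = mesh.n_faces
    k = min(params.k_nn + 1, m)
    dist, idx = cKDTree(cents).query(cents, k=k)
    rows = np.repeat(np.arange(m), k)
    cols = idx.ravel()
    d2 = (dist.ravel()) ** 2
    sigma_m = params.sigma_m
    if sigma_m is None:
        nz = dist[:, 1:]
        sigma_m = float(nz.mean()) if nz.size else 1.0
    nd2 = ((normals[rows] - normals[cols]) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2 * sigma_m**2)) * np.exp(-nd2 / (2 * params.sigma_n**2))
    C_w = sp.coo_matrix((w, (rows, cols)), shape=(m, m)).tocsr()
    rs = np.asarray(C_w.sum(axis=1)).ravel()
    dead = rs <= 0
    if dead.any():
        warnings.warn("zero-weight rows: those faces keep their input normal",
                      RuntimeWarning, stacklevel=2)
        rs[dead] = 1.0
    op = sp.diags(1.0 / rs) @ C_w
    out = normals.copy()
    for _ in range(params.zeta):
        out = op @ out
    out[dead] = normals[dead]
    norms = np.linalg.norm(out, axis=1)
    zero = norms < 1e-300
    out[zero] = normals[zero]
    norms[zero] = 1.0
    return out / norms[:, None]


def vertex_update_from_normals(
    mesh: TriangleMesh, filtered_normals: np.ndarray, iterations: int = 5
) -> TriangleMesh:
    """Move vertices to agree with filtered face normals.

    Each iteration: ``v_i += mean_{j in faces(i)} n_j <n_j, m_j - v_i>``
    with face centroids refreshed from the updated vertices.  A perfect
    plane with exact normals is a fixed point (the projector vanishes).
    """
    filtered_normals = np.asarray(filtered_normals, float)
    verts = mesh.vertices.copy()
    incidence = mesh.vertex_face_incidence()
    counts = np.asarray(incidence.sum(axis=1)).ravel()
    ok = counts > 0
    inv = np.zeros_like(counts)
    inv[ok] = 1.0 / counts[ok]
    for _ in range(iterations):
        cents = verts[mesh.faces].mean(axis=1)
        # s_j(i) = <n_j, m_j - v_i> split into <n_j, m_j> and <n_j, v_i>
        nm = np.einsum("ij,ij->i", filtered_normals, cents)
        a = incidence @ (filtered_normals * nm[:, None])  # sum n_j <n_j, m_j>
        # the <n_j, v_i> part couples v_i with the incident-face projector
        # sum_j n_j n_j^T
        nnT = np.einsum("ja,jb->jab", filtered_normals, filtered_normals)
        M = np.stack(
            [incidence @ nnT[:, a, :] for a in range(3)], axis=1
        )  # (n, 3, 3): sum_j n_j n_j^T over incident faces
        proj = np.einsum("iab,ib->ia", M, verts)
        verts = verts + inv[:, None] * (a - proj)
    return mesh.with_vertices(verts)


def taubin_smooth(
    mesh: TriangleMesh,
    lam: float = 0.33,
    mu: float = -0.34,
    iterations: int = 10,
    anchors: np.ndarray | None = None,
) -> TriangleMesh:
    """Alternating lambda/mu uniform-Laplacian steps; anchors held fixed."""
    if not (0 < lam < -mu < 1):
        raise ValueError("require 0 < lambda < -mu < 1")
    e = mesh.edges_unique
    n = mesh.n_vertices
    ones = np.ones(len(e))
    A = sp.coo_matrix((ones, (e[:, 0], e[:, 1])), shape=(n, n))
    A = (A + A.T).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    avg = sp.diags(1.0 / deg) @ A
    free = np.ones(n, dtype=bool)
    if anchors is not None:
        free[np.asarray(anchors, dtype=np.int64)] = False
    verts = mesh.vertices.copy()
    for _ in range(iterations):
        for step in (lam, mu):
            delta = avg @ verts - verts
            verts[free] += step * delta[free]
    return mesh.with_vertices(verts)
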