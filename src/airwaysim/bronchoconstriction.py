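"""Ratio-targeted regional narrowing of an airway surface.

The bronchoconstriction loop contracts a selected face region of the mesh
toward its centerline until the shape-diameter narrowing ratio reaches a
user target.  One run:

1. initialize ``W_L = k * omega * sqrt(A)`` (k = 1e-3, A = mean face area)
   and ``W_H = I``;
2. solve the constrained contraction least-squares problem for new vertex
   positions of the region;
3. amplify ``W_L`` by ``s_L`` and rescale each anchor weight by
   ``sqrt(A_i^0 / A_i^t)``;
4. recompute the cotangent Laplacian on the deformed region;
5. recompute the narrowing ratio ``r_t`` (SDF sum after / before);
6. repeat 2–5 while ``r_t > r + e`` and the iteration budget allows.

Only vertices of the selected region enter the linear system; the region's
one-ring boundary is softly anchored with a large weight, and everything
outside the region does not move at all.  An optional abnormality profile
modulates the contraction weight per vertex as a function of geodesic
distance from the region boundary, producing non-uniform, wavy narrowing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .contraction import (
    ContractionState,
    ContractionWeights,
    contraction_solve,
    update_weights,
    DEFAULT_K,
    DEFAULT_S_L,
)
from .mesh import (
    TriangleMesh,
    cotangent_laplacian,
    enclosed_volume,
    face_areas,
    one_ring_areas,
)
from .sdf_segmentation import SdfField, narrowing_ratio, raw_sdf

__all__ = [
    "NarrowingSpec",
    "AbnormalityWeights",
    "NarrowingResult",
    "simulate_bronchoconstriction",
    "geodesic_distance",
    "abnormality_weights",
]

#: anchor-weight multiplier for the region's one-ring boundary vertices
BOUNDARY_ANCHOR = 1.0e3


@dataclass
class NarrowingSpec:
    """Target ratio ``r``, tolerance ``e``, budget ``t``, weight ``omega``,
    the face region to constrict and an optional abnormality profile."""

    r: float = 0.5
    e: float = 0.05
    t: int = 8
    omega: float = 0.8
    region: np.ndarray | None = None
    abnormality: bool = False
    abnormality_fn: object = None
    wavenumber: float | None = None
    s_L: float | str = "auto"
    k: float = DEFAULT_K
    n_rays: int = 25
    max_solves_per_iteration: int = 12

    def __post_init__(self):
        if not 0 < self.r < 1:
            raise ValueError("target ratio r must lie in (0, 1)")
        if self.e < 0:
            raise ValueError("accepted error e must be non-negative")
        if self.r + self.e >= 1:
            raise ValueError("r + e must be below 1")
        if self.t < 1:
            raise ValueError("iteration budget t must be >= 1")
        if not 0 <= self.omega <= 1:
            raise ValueError("omega must lie in [0, 1]")


@dataclass
class AbnormalityWeights:
    """Per-vertex diagonal modulation of the contraction weight."""

    W_V: np.ndarray
    d: np.ndarray


@dataclass
class NarrowingResult:
    mesh: TriangleMesh
    achieved_ratio: float
    converged: bool
    iterations: int
    log: list = dfield(default_factory=list)  # (iteration, ratio, volume)
    field_before: SdfField | None = None
    field_after: SdfField | None = None


def geodesic_distance(mesh: TriangleMesh, anchors) -> np.ndarray:
    """Graph geodesic (shortest path along edges) from the nearest anchor.

    Disconnected components without an anchor get ``inf`` with a warning.
    """
    anchors = np.atleast_1d(np.asarray(anchors, dtype=np.int64))
    if len(anchors) == 0:
        raise ValueError("at least one anchor vertex is required")
    e = mesh.edges_unique
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    g = sp.coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
    g = g + g.T
    d = dijkstra(g.tocsr(), directed=False, indices=anchors, min_only=True)
    if np.isinf(d).any():
        warnings.warn(
            "mesh components with no anchor: geodesic distance is inf there",
            RuntimeWarning,
            stacklevel=2,
        )
    return d


def abnormality_weights(
    d: np.ndarray, omega: float, wavenumber: float = 1.0, fn=None
) -> AbnormalityWeights:
    """Sinusoidal (or user-supplied) weighting of the contraction by
    geodesic distance: ``W_V = omega + (1 - omega)/2 * sin(kappa d)``.

    ``omega = 1`` collapses to no modulation.  ``kappa`` rescales the
    sinusoid argument so the spatial period is resolution-independent.
    Non-positive weights (possible for ``omega < 1/3``) are floored.
    """
    if not 0 <= omega <= 1:
        raise ValueError("omega must lie in [0, 1]")
    d = np.asarray(d, float)
    if fn is not None:
        wv = np.asarray(fn(d), float)
    else:
        wv = omega + (1.0 - omega) / 2.0 * np.sin(wavenumber * d)
    floor = 1e-6
    if (wv < floor).any():
        warnings.warn("abnormality weights floored at 1e-6", RuntimeWarning,
                      stacklevel=2)
        wv = np.maximum(wv, floor)
    return AbnormalityWeights(W_V=wv, d=d)


def _region_submesh(mesh: TriangleMesh, region: np.ndarray):
    """Submesh of the region faces; returns (submesh, vertex ids, boundary)."""
    region = np.asarray(region, dtype=np.int64)
    faces = mesh.faces[region]
    vids = np.unique(faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[vids] = np.arange(len(vids))
    sub = TriangleMesh(mesh.vertices[vids], remap[faces])
    # boundary: vertices on submesh boundary edges, or shared with faces
    # outside the region
    e = sub.edges_unique
    counts = sub._edge_cache["edge_counts"]
    boundary_local = np.unique(e[counts == 1])
    outside = np.ones(mesh.n_faces, dtype=bool)
    outside[region] = False
    shared = np.intersect1d(vids, np.unique(mesh.faces[outside]))
    boundary = np.union1d(vids[boundary_local], shared)
    return sub, vids, remap, np.isin(vids, boundary)


def simulate_bronchoconstriction(
    mesh: TriangleMesh, spec: NarrowingSpec
) -> NarrowingResult:
    """Run the narrowing loop on ``spec.region`` of ``mesh``.

    Returns the deformed mesh (only region vertices moved), the achieved
    ratio, and a per-iteration (ratio, enclosed volume) log.  If the target
    band is not reached within the budget the best mesh is returned with
    ``converged=False`` rather than raising.
    """
    if spec.region is None:
        raise ValueError("spec.region must list the faces to constrict")
    region = np.asarray(spec.region, dtype=np.int64)
    sub, vids, _remap, is_boundary = _region_submesh(mesh, region)

    # Work in units where the model's mean face area is 1: cotangent weights
    # and the SDF ratio are scale-invariant, and this makes the balance
    # between the k = 1e-3 contraction weight and the unit anchor weights
    # independent of mesh resolution and physical units.
    A_mean = float(face_areas(mesh).mean())
    scale = 1.0 / np.sqrt(A_mean)
    sub = sub.with_vertices(sub.vertices * scale)
    W_L0 = spec.k * spec.omega  # Eq. balance at unit mean face area
    W_H0 = np.ones(sub.n_vertices)
    W_H0[is_boundary] = BOUNDARY_ANCHOR

    if spec.abnormality:
        d = geodesic_distance(sub, np.flatnonzero(is_boundary))
        finite = d[np.isfinite(d)]
        kappa = spec.wavenumber
        if kappa is None:
            kappa = 2.0 * np.pi / max(float(finite.max()), 1e-12)
        ab = abnormality_weights(d, spec.omega, kappa, fn=spec.abnormality_fn)
        profile = ab.W_V / float(ab.W_V.max())
        W_L = W_L0 * profile
    else:
        profile = 1.0
        W_L = W_L0

    auto = spec.s_L == "auto"
    s_L = DEFAULT_S_L if auto else float(spec.s_L)
    weights = ContractionWeights(W_L, W_H0, s_L=s_L, k=spec.k,
                                 omega=spec.omega)
    anchors = sub.vertices.copy()
    state = ContractionState(
        mesh=sub,
        iteration=0,
        initial_one_ring=one_ring_areas(sub),
        anchors=anchors,
        volume_history=[],
    )

    field_before = raw_sdf(sub, n_rays=spec.n_rays)
    sdf_before = float(np.nansum(field_before.raw))
    ratio = 1.0
    log = []
    full_vertices = mesh.vertices.copy()

    def _compose():
        full_vertices[vids] = state.mesh.vertices / scale
        return mesh.with_vertices(full_vertices.copy())

    def _solve_ratio(w_l):
        w = weights.copy()
        w.W_L = w_l * profile
        L = cotangent_laplacian(state.mesh)
        new_v = contraction_solve(state.mesh, L, w, anchors)
        cand = state.mesh.with_vertices(new_v)
        f = raw_sdf(cand, n_rays=spec.n_rays)
        return cand, float(np.nansum(f.raw)) / sdf_before, f

    w_scalar = float(np.max(weights.W_L))
    field_after = field_before
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        while state.iteration < spec.t:
            if auto:
                # line search on the amplification: grow W_L monotonically,
                # log-bisect when a candidate would overshoot below r - e
                lo, hi = None, None
                cand_w = w_scalar * 32.0
                best = None
                for _ in range(spec.max_solves_per_iteration):
                    cand_mesh, cand_r, cand_f = _solve_ratio(cand_w)
                    if cand_r < spec.r - spec.e:          # overshoot
                        hi = cand_w
                        cand_w = np.sqrt(lo * hi) if lo is not None else cand_w / 8.0
                    elif cand_r > max(spec.r + spec.e, 0.97 * ratio):
                        # insufficient progress: amplify further
                        best = (cand_mesh, cand_r, cand_w, cand_f)
                        lo = cand_w
                        cand_w = cand_w * 32.0 if hi is None else np.sqrt(lo * hi)
                    else:
                        best = (cand_mesh, cand_r, cand_w, cand_f)
                        break
                if best is None:
                    break  # every candidate overshot; keep current mesh
                new_mesh, ratio, w_scalar, field_after = best
            else:
                w_scalar = w_scalar * weights.s_L
                new_mesh, ratio, field_after = _solve_ratio(w_scalar)
            state.mesh = new_mesh
            state.iteration += 1
            weights = update_weights(weights, state, W_H0=W_H0)
            weights.W_L = w_scalar  # amplification is owned by the schedule
            composed = _compose()
            vol = enclosed_volume(composed) if composed.is_watertight else np.nan
            log.append((state.iteration, ratio, vol))
            if ratio <= spec.r + spec.e:
                converged = True
                break

    if not converged:
        warnings.warn(
            f"narrowing target {spec.r}+{spec.e} not reached in {spec.t} "
            f"iterations (achieved {ratio:.3f})",
            RuntimeWarning,
            stacklevel=2,
        )
    return NarrowingResult(
        mesh=_compose(),
        achieved_ratio=ratio,
        converged=converged,
        iterations=state.iteration,
        log=log,
        field_before=field_before,
        field_after=field_after if log else field_before,
    )
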