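"""Constrained Laplacian mesh contraction.

The engine shrinks a surface along its inward curvature-normal direction by
repeatedly solving the sparse least-squares problem

    minimize  || W_L L V ||^2  +  sum_j W_H,j^2 || V_j - V_a,j ||^2

per coordinate, where ``L`` is the cotangent Laplacian of the *current*
mesh, ``W_L`` a (scalar or per-vertex) contraction weight, and ``W_H``
diagonal anchor weights pulling vertices back toward their positions at the
start of the iteration scheme.  Between iterations the contraction weight is
amplified (``W_L <- s_L W_L``) and each anchor weight is rescaled by
``sqrt(A_i^0 / A_i^t)``, the square-root ratio of the vertex's initial to
current one-ring area, so collapsing regions are progressively released.

Used in two modes: contraction to (near) zero volume for skeleton
extraction, and ratio-targeted regional contraction for bronchoconstriction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import (
    TriangleMesh,
    cotangent_laplacian,
    enclosed_volume,
    face_areas,
    one_ring_areas,
)

__all__ = [
    "ContractionWeights",
    "ContractionState",
    "initial_weights",
    "contraction_solve",
    "update_weights",
    "contract_iterative",
    "VolumeThreshold",
    "MaxIterations",
]

#: default per-iteration amplification of the contraction weight
DEFAULT_S_L = 2.0
#: base constant k of W_L = k * omega * sqrt(A)
DEFAULT_K = 1.0e-3
#: collapsed one-ring areas are clamped at this fraction of their initial value
AREA_FLOOR = 1.0e-12


@dataclass
class ContractionWeights:
    """Weights of the contraction solve.

    ``W_L`` may be a scalar or a per-vertex vector (after modulation by an
    abnormality profile); ``W_H`` is always per-vertex.
    """

    W_L: np.ndarray | float
    W_H: np.ndarray
    s_L: float = DEFAULT_S_L
    k: float = DEFAULT_K
    omega: float = 1.0

    def __post_init__(self) -> None:
        self.W_H = np.asarray(self.W_H, dtype=float)
        if np.any(self.W_H <= 0):
            raise ValueError("anchor weights W_H must be positive")
        if np.any(np.asarray(self.W_L) <= 0):
            raise ValueError("contraction weight W_L must be positive")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")

    def copy(self) -> "ContractionWeights":
        wl = self.W_L if np.isscalar(self.W_L) else np.array(self.W_L)
        return ContractionWeights(wl, self.W_H.copy(), self.s_L, self.k, self.omega)


@dataclass
class ContractionState:
    """Evolving mesh plus the bookkeeping the weight updates need."""

    mesh: TriangleMesh
    iteration: int
    initial_one_ring: np.ndarray
    anchors: np.ndarray
    volume_history: list = field(default_factory=list)
    converged: bool = True
    warning: str | None = None


def initial_weights(
    mesh: TriangleMesh,
    omega: float = 1.0,
    k: float = DEFAULT_K,
    s_L: float = DEFAULT_S_L,
    W_H: np.ndarray | None = None,
) -> ContractionWeights:
    """``W_L = k * omega * sqrt(A)`` (A = mean face area), ``W_H = I``."""
    A = float(face_areas(mesh).mean())
    if W_H is None:
        W_H = np.ones(mesh.n_vertices)
    return ContractionWeights(k * omega * np.sqrt(A), np.asarray(W_H, float),
                              s_L=s_L, k=k, omega=omega)


def contraction_solve(
    mesh: TriangleMesh,
    L: sp.spmatrix,
    weights: ContractionWeights,
    anchors: np.ndarray,
) -> np.ndarray:
    """One least-squares contraction step; returns new vertex positions.

    Solves the normal equations (A^T A) V' = A^T b with
    A = [W_L L; diag(W_H)], b = [0; W_H * V_a], sharing one sparse
    factorization across the x, y, z coordinates.
    """
    anchors = np.asarray(anchors, float)
    wl = weights.W_L
    WL_L = (sp.diags(wl) @ L) if not np.isscalar(wl) else (wl * L)
    wh2 = weights.W_H**2
    M = (WL_L.T @ WL_L + sp.diags(wh2)).tocsc()
    rhs = wh2[:, None] * anchors
    try:
        solver = spla.splu(M)
    except RuntimeError as exc:  # singular normal equations
        raise np.linalg.LinAlgError(f"contraction system is singular: {exc}")
    return np.column_stack([solver.solve(rhs[:, c]) for c in range(3)])


def update_weights(
    weights: ContractionWeights,
    state: ContractionState,
    W_H0: np.ndarray | None = None,
) -> ContractionWeights:
    """Amplify W_L by s_L; rescale anchors by sqrt(A_i^0 / A_i^t)."""
    new = weights.copy()
    new.W_L = new.W_L * weights.s_L
    current = one_ring_areas(state.mesh)
    floor = AREA_FLOOR * state.initial_one_ring
    if (current < floor).any():
        warnings.warn(
            "collapsed one-rings: areas clamped in anchor-weight update",
            RuntimeWarning,
            stacklevel=2,
        )
        current = np.maximum(current, floor)
    base = weights.W_H if W_H0 is None else np.asarray(W_H0, float)
    new.W_H = base * np.sqrt(state.initial_one_ring / current)
    return new


# -- termination policies --------------------------------------------------

@dataclass
class VolumeThreshold:
    """Stop when enclosed volume / initial volume drops below ``threshold``."""

    threshold: float = 1.0e-7

    def __call__(self, state: ContractionState) -> bool:
        return (
            abs(state.volume_history[-1]) / abs(state.volume_history[0])
            < self.threshold
        )


@dataclass
class MaxIterations:
    """Stop after a fixed number of iterations (0 = no-op)."""

    n: int

    def __call__(self, state: ContractionState) -> bool:
        return state.iteration >= self.n


def contract_iterative(
    mesh: TriangleMesh,
    weights: ContractionWeights | None = None,
    stop=VolumeThreshold(),
    hard_cap: int = 50,
) -> ContractionState:
    """Run {recompute L, solve, update weights} until the policy fires.

    The anchor positions fed to each solve are the vertex positions at the
    *start* of the scheme; the volume history is recorded every iteration.
    A ``hard_cap`` bounds the loop; if it is reached before the policy
    fires, the best state is returned with ``converged=False``.
    """
    if weights is None:
        weights = initial_weights(mesh)
    work = mesh.copy()
    anchors = work.vertices.copy()
    state = ContractionState(
        mesh=work,
        iteration=0,
        initial_one_ring=one_ring_areas(work),
        anchors=anchors,
        volume_history=[enclosed_volume(work)],
    )
    W_H0 = weights.W_H.copy()
    if stop(state):
        return state
    enforce_monotone = isinstance(stop, VolumeThreshold)
    while state.iteration < hard_cap:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            L = cotangent_laplacian(state.mesh)
            new_v = contraction_solve(state.mesh, L, weights, anchors)
            candidate = state.mesh.with_vertices(new_v)
            vol = enclosed_volume(candidate)
            state.iteration += 1
            if enforce_monotone and abs(vol) > abs(state.volume_history[-1]):
                # reject volume-increasing steps (late-stage degenerate
                # triangles can destabilize the solve); amplify W_L and retry
                state.volume_history.append(state.volume_history[-1])
                w2 = weights.copy()
                w2.W_L = weights.W_L * weights.s_L
                weights = w2
            else:
                state.mesh = candidate
                state.volume_history.append(vol)
                weights = update_weights(weights, state, W_H0=W_H0)
        if stop(state):
            return state
    state.converged = False
    state.warning = f"termination policy not met within {hard_cap} iterations"
    warnings.warn(state.warning, RuntimeWarning, stacklevel=2)
    return state
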