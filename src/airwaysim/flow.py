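"""Prescribed velocity fields for the airway tree.

A full Navier–Stokes solution is outside the scope of this package: the
particle tracker consumes any object satisfying the :class:`FlowField`
contract (velocity at points, fluid density and viscosity).  Three concrete
fields are provided:

* :class:`UniformField` — constant velocity (test oracle / settling studies).
* :class:`PoiseuilleTreeField` — fully developed parabolic profile in every
  segment of an :class:`AirwayTreeGraph`, with flowrates conserved at each
  junction and linear blending within one radius of junction points.
* :class:`RegularGridField` — trilinear interpolation of an externally
  computed velocity field sampled on a regular grid (e.g. imported from a
  CFD solution via legacy-VTK structured points).

Fluid defaults are air at 20 °C.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "AIR_DENSITY",
    "AIR_VISCOSITY",
    "FlowField",
    "UniformField",
    "PoiseuilleTreeField",
    "RegularGridField",
    "AirwaySegment",
    "AirwayTreeGraph",
    "split_flow",
    "poiseuille_tree_field",
    "uniform_field",
]

AIR_DENSITY = 1.204       # kg/m^3, 20 degC
AIR_VISCOSITY = 1.81e-5   # Pa s


class FlowField:
    """Velocity-at-point contract plus fluid properties."""

    rho: float
    mu: float

    def velocity(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def in_domain(self, points: np.ndarray) -> np.ndarray:
        return np.ones(len(np.atleast_2d(points)), dtype=bool)

    def vorticity(self, points: np.ndarray, h: float = 1e-6) -> np.ndarray:
        """Curl of the velocity by central differences (override if analytic)."""
        p = np.atleast_2d(np.asarray(points, float))
        grad = np.zeros((len(p), 3, 3))
        for a in range(3):
            dp = np.zeros(3)
            dp[a] = h
            grad[:, :, a] = (self.velocity(p + dp) - self.velocity(p - dp)) / (2 * h)
        curl = np.column_stack([
            grad[:, 2, 1] - grad[:, 1, 2],
            grad[:, 0, 2] - grad[:, 2, 0],
            grad[:, 1, 0] - grad[:, 0, 1],
        ])
        return curl


@dataclass
class UniformField(FlowField):
    u: np.ndarray = dfield(default_factory=lambda: np.zeros(3))
    rho: float = AIR_DENSITY
    mu: float = AIR_VISCOSITY

    def __post_init__(self):
        self.u = np.asarray(self.u, float)

    def velocity(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.broadcast_to(self.u, (len(p), 3)).copy()

    def vorticity(self, points: np.ndarray, h: float = 1e-6) -> np.ndarray:
        return np.zeros((len(np.atleast_2d(points)), 3))


def uniform_field(u, rho: float = AIR_DENSITY, mu: float = AIR_VISCOSITY) -> UniformField:
    return UniformField(np.asarray(u, float), rho, mu)


# ---------------------------------------------------------------------------
# airway tree graph
# ---------------------------------------------------------------------------

@dataclass
class AirwaySegment:
    """Straight airway segment: a cylinder from ``start`` to ``end``."""

    start: np.ndarray
    end: np.ndarray
    radius: float
    generation: int
    side: str = ""            # "left" / "right" / "" (trachea)
    parent: int | None = None
    children: list = dfield(default_factory=list)
    flowrate: float = 0.0     # m^3/s
    segment_id: int = 0

    def __post_init__(self):
        self.start = np.asarray(self.start, float)
        self.end = np.asarray(self.end, float)
        if self.radius <= 0:
            raise ValueError("segment radius must be positive")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def axis(self) -> np.ndarray:
        return (self.end - self.start) / self.length

    @property
    def is_outlet(self) -> bool:
        return len(self.children) == 0


@dataclass
class AirwayTreeGraph:
    """Centerline tree with radii, generation/side tags and flowrates."""

    segments: list
    inlet_flowrate: float = 0.0

    @property
    def root(self) -> AirwaySegment:
        return next(s for s in self.segments if s.parent is None)

    def outlets(self) -> list:
        return [s for s in self.segments if s.is_outlet]

    def check_conservation(self, rtol: float = 1e-10) -> bool:
        for s in self.segments:
            if s.children:
                q = sum(self.segments[c].flowrate for c in s.children)
                if abs(q - s.flowrate) > rtol * max(abs(s.flowrate), 1e-300):
                    return False
        return True

    def scaled_radii(self, scale_map: dict) -> "AirwayTreeGraph":
        """Copy of the tree with per-segment radial scales applied."""
        segs = []
        for s in self.segments:
            scale = scale_map.get(s.segment_id, 1.0)
            segs.append(
                AirwaySegment(
                    s.start.copy(), s.end.copy(), s.radius * scale,
                    s.generation, s.side, s.parent, list(s.children),
                    s.flowrate, s.segment_id,
                )
            )
        return AirwayTreeGraph(segs, self.inlet_flowrate)


def split_flow(
    tree: AirwayTreeGraph, inlet_flowrate: float, rule: str = "resistance"
) -> AirwayTreeGraph:
    """Assign conserved flowrates down the tree.

    ``equal`` splits every junction evenly; ``resistance`` splits in
    proportion to Poiseuille conductance R^4 / L, so narrowing a branch
    starves it of flow (the R^4 law).
    """
    if rule not in ("equal", "resistance"):
        raise ValueError(f"unknown split rule {rule!r}")
    for s in tree.segments:
        if s.radius <= 0:
            raise ValueError(f"segment {s.segment_id} has non-positive radius")
    tree.inlet_flowrate = float(inlet_flowrate)
    root = tree.root
    root.flowrate = float(inlet_flowrate)
    stack = [root]
    while stack:
        s = stack.pop()
        if not s.children:
            continue
        kids = [tree.segments[c] for c in s.children]
        if rule == "equal":
            wts = np.ones(len(kids))
        else:
            wts = np.array([k.radius**4 / k.length for k in kids])
        wts = wts / wts.sum()
        for k, w in zip(kids, wts):
            k.flowrate = s.flowrate * float(w)
            stack.append(k)
    return tree


# ---------------------------------------------------------------------------
# Poiseuille field on a tree
# ---------------------------------------------------------------------------

class PoiseuilleTreeField(FlowField):
    """Axial parabolic profile per segment, blended near junctions.

    Inside segment ``k`` at radial distance ``r`` from its axis the axial
    velocity is ``2 q_k / (pi R_k^2) * (1 - (r/R_k)^2)`` (centerline = twice
    the mean, zero at the wall).  Within one radius of a segment end the
    segment's contribution ramps down linearly and overlapping segments are
    weight-averaged, which keeps the field continuous across junctions.
    Points inside no segment get zero velocity and are flagged out-of-domain.
    """

    def __init__(self, tree: AirwayTreeGraph, rho: float = AIR_DENSITY,
                 mu: float = AIR_VISCOSITY):
        if not tree.check_conservation():
            raise ValueError("tree flowrates do not conserve at junctions")
        self.tree = tree
        self.rho = rho
        self.mu = mu
        segs = tree.segments
        self._starts = np.array([s.start for s in segs])
        self._axes = np.array([s.axis for s in segs])
        self._lengths = np.array([s.length for s in segs])
        self._radii = np.array([s.radius for s in segs])
        self._umean = np.array(
            [s.flowrate / (np.pi * s.radius**2) for s in segs]
        )

    def _weights_and_velocities(self, p: np.ndarray):
        rel = p[:, None, :] - self._starts[None, :, :]          # (n, m, 3)
        s_ax = np.einsum("nmj,mj->nm", rel, self._axes)          # axial coord
        radial = rel - s_ax[..., None] * self._axes[None, :, :]
        r = np.linalg.norm(radial, axis=2)
        R = self._radii[None, :]
        L = self._lengths[None, :]
        inside_r = r <= R
        over = np.maximum(np.maximum(-s_ax, s_ax - L), 0.0)     # axial overhang
        w = np.clip(1.0 - over / R, 0.0, 1.0) * inside_r
        prof = 2.0 * self._umean[None, :] * np.clip(1.0 - (r / R) ** 2, 0.0, None)
        u_seg = prof[..., None] * self._axes[None, :, :]
        return w, u_seg

    def velocity(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        w, u_seg = self._weights_and_velocities(p)
        tot = w.sum(axis=1)
        u = np.einsum("nm,nmj->nj", w, u_seg)
        ok = tot > 0
        u[ok] /= tot[ok, None]
        u[~ok] = 0.0
        return u

    def in_domain(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        w, _ = self._weights_and_velocities(p)
        return w.sum(axis=1) > 0


def poiseuille_tree_field(tree: AirwayTreeGraph, rho: float = AIR_DENSITY,
                          mu: float = AIR_VISCOSITY) -> PoiseuilleTreeField:
    return PoiseuilleTreeField(tree, rho, mu)


# ---------------------------------------------------------------------------
# tabulated fields
# ---------------------------------------------------------------------------

class RegularGridField(FlowField):
    """Trilinear interpolation of velocity samples on a regular grid."""

    def __init__(self, origin, spacing, values, rho: float = AIR_DENSITY,
                 mu: float = AIR_VISCOSITY):
        values = np.asarray(values, float)  # (nx, ny, nz, 3)
        origin = np.asarray(origin, float)
        spacing = np.asarray(spacing, float)
        axes = [
            origin[a] + spacing[a] * np.arange(values.shape[a]) for a in range(3)
        ]
        self._interp = RegularGridInterpolator(
            axes, values, bounds_error=False, fill_value=0.0
        )
        self.origin, self.spacing, self.values = origin, spacing, values
        self.rho, self.mu = rho, mu

    def velocity(self, points: np.ndarray) -> np.ndarray:
        return self._interp(np.atleast_2d(np.asarray(points, float)))
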