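"""Synthetic airway geometry: parametric bifurcating trees and cylinders.

The generator emulates a central-airway model down to a configurable number
of bifurcating generations: a trachea splitting into left and right main
bronchi and onward, with Weibel-like defaults (child/parent diameter ratio
2^(-1/3), length three diameters, 35 degree branching half-angle).  The
surface is built as the zero level set of the union of capsule signed
distance fields sampled on a regular grid and triangulated with marching
cubes, which guarantees a watertight mesh across junctions.  Every face is
labelled with its airway segment, generation, left/right side and whether
it belongs to an outlet cap; the matching centerline graph with ground-truth
radii is returned alongside.

Generation convention: ``generations = G`` produces a trachea plus ``G``
bifurcation levels, i.e. ``2**G`` outlets; ``generations = 0`` is a single
capped tube.  The trachea is tagged ``upper``; branch levels are tagged
``gen1`` .. ``genG``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from skimage import measure

from .flow import AirwaySegment, AirwayTreeGraph
from .mesh import TriangleMesh, centroids, enclosed_volume
from .sdf_segmentation import SegmentLabels

__all__ = [
    "TreeSpec",
    "generate_tree",
    "generate_cylinder",
    "apply_known_narrowing",
]


@dataclass
class TreeSpec:
    """Parameters of the synthetic bronchial tree (meters, degrees)."""

    generations: int = 5
    root_diameter: float = 0.016
    diameter_ratio: float = 2.0 ** (-1.0 / 3.0)
    length_over_diameter: float = 3.0
    half_angle_deg: float = 35.0
    mesh_resolution: float | None = None   # target edge length; default D0/16
    seed: int = 0
    narrowing: dict = dfield(default_factory=dict)  # segment id -> radial scale
    asymmetry: float = 0.0  # right/left diameter skew in (−1, 1)

    def __post_init__(self):
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0 < self.diameter_ratio <= 1:
            raise ValueError("diameter ratio must lie in (0, 1]")
        for s in self.narrowing.values():
            if not 0 < s <= 1:
                raise ValueError("radial scales must lie in (0, 1]")


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def _build_centerline(spec: TreeSpec) -> AirwayTreeGraph:
    r0 = spec.root_diameter / 2.0
    L0 = spec.length_over_diameter * spec.root_diameter
    root = AirwaySegment(
        start=(0.0, 0.0, 0.0), end=(0.0, 0.0, -L0), radius=r0,
        generation=0, side="", parent=None, segment_id=0,
    )
    segments = [root]
    theta = np.radians(spec.half_angle_deg)
    # (segment index, direction, branch-plane normal)
    frontier = [(0, np.array([0.0, 0.0, -1.0]), np.array([0.0, 1.0, 0.0]))]
    for gen in range(1, spec.generations + 1):
        nxt = []
        for parent_idx, d, b in frontier:
            parent = segments[parent_idx]
            for sign in (+1, -1):
                d_child = _rotate(d, b, sign * theta)
                skew = 1.0 + spec.asymmetry * (1 if sign > 0 else -1)
                radius = parent.radius * spec.diameter_ratio * skew
                length = spec.length_over_diameter * 2 * radius
                if gen == 1:
                    side = "right" if sign > 0 else "left"
                else:
                    side = parent.side
                seg = AirwaySegment(
                    start=parent.end.copy(),
                    end=parent.end + d_child * length,
                    radius=radius,
                    generation=gen,
                    side=side,
                    parent=parent_idx,
                    segment_id=len(segments),
                )
                parent.children.append(seg.segment_id)
                segments.append(seg)
                # successive branching planes are perpendicular
                b_child = np.cross(d_child, b)
                b_child /= np.linalg.norm(b_child)
                nxt.append((seg.segment_id, d_child, b_child))
        frontier = nxt
    return AirwayTreeGraph(segments)


def _segment_distance(points: np.ndarray, seg: AirwaySegment, radius: float):
    """Signed capsule distance (negative inside) and axial coordinate."""
    rel = points - seg.start
    axis = seg.axis
    s = rel @ axis
    s_cl = np.clip(s, 0.0, seg.length)
    closest = seg.start + s_cl[:, None] * axis
    return np.linalg.norm(points - closest, axis=1) - radius, s


def _effective_radius(seg: AirwaySegment, narrowing: dict) -> float:
    return seg.radius * narrowing.get(seg.segment_id, 1.0)


def generate_tree(
    spec: TreeSpec,
) -> tuple[TriangleMesh, SegmentLabels, AirwayTreeGraph]:
    """Watertight labelled tree surface + centerline graph with radii."""
    tree = _build_centerline(spec)
    pitch = spec.mesh_resolution or spec.root_diameter / 16.0

    ends = np.array([s.end for s in tree.segments] + [s.start for s in tree.segments])
    rmax = max(s.radius for s in tree.segments)
    lo = ends.min(axis=0) - rmax - 3 * pitch
    hi = ends.max(axis=0) + rmax + 3 * pitch
    shape = np.maximum(np.ceil((hi - lo) / pitch).astype(int) + 1, 2)

    sdf = np.full(shape, np.inf, dtype=np.float32)
    axes = [lo[a] + pitch * np.arange(shape[a]) for a in range(3)]
    for seg in tree.segments:
        radius = _effective_radius(seg, spec.narrowing)
        pad = radius + 2 * pitch
        smin = np.minimum(seg.start, seg.end) - pad
        smax = np.maximum(seg.start, seg.end) + pad
        i0 = np.maximum(((smin - lo) / pitch).astype(int), 0)
        i1 = np.minimum(((smax - lo) / pitch).astype(int) + 2, shape)
        gx, gy, gz = np.meshgrid(
            axes[0][i0[0]:i1[0]], axes[1][i0[1]:i1[1]], axes[2][i0[2]:i1[2]],
            indexing="ij",
        )
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        d, _ = _segment_distance(pts, seg, radius)
        block = sdf[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        np.minimum(block, d.reshape(block.shape).astype(np.float32), out=block)

    verts, faces, _normals, _vals = measure.marching_cubes(
        sdf, level=0.0, spacing=(pitch, pitch, pitch)
    )
    verts = verts + lo
    mesh = TriangleMesh(verts, faces.astype(np.int64))
    if enclosed_volume(mesh) < 0:
        mesh = TriangleMesh(verts, faces[:, ::-1].astype(np.int64))

    labels = label_faces(mesh, tree, spec.narrowing)
    return mesh, labels, tree


def label_faces(
    mesh: TriangleMesh, tree: AirwayTreeGraph, narrowing: dict | None = None
) -> SegmentLabels:
    """Assign each face to a segment; derive region/side/outlet tags.

    Faces in the junction collar (within one parent radius of a segment's
    proximal end) are assigned to the parent airway, so the carina saddle
    between the main bronchi counts as part of the trachea.  Faces beyond
    the distal end of a terminal segment form its outlet cap.
    """
    narrowing = narrowing or {}
    cents = centroids(mesh)
    n = len(cents)
    best_d = np.full(n, np.inf)
    best_seg = np.zeros(n, dtype=np.int64)
    axial = np.zeros(n)
    for seg in tree.segments:
        d, s = _segment_distance(cents, seg, _effective_radius(seg, narrowing))
        closer = d < best_d
        best_d[closer] = d[closer]
        best_seg[closer] = seg.segment_id
        axial[closer] = s[closer]

    seg_ids = best_seg.copy()
    for seg in tree.segments:
        if seg.parent is None:
            continue
        collar = tree.segments[seg.parent].radius
        mask = (best_seg == seg.segment_id) & (axial < collar)
        seg_ids[mask] = seg.parent

    region = np.empty(n, dtype=object)
    side = np.empty(n, dtype=object)
    for seg in tree.segments:
        mask = seg_ids == seg.segment_id
        region[mask] = "upper" if seg.generation == 0 else f"gen{seg.generation}"
        side[mask] = seg.side
        if seg.is_outlet:
            cap = mask & (axial > seg.length) & (best_seg == seg.segment_id)
            region[cap] = "outlet"
    return SegmentLabels(labels=seg_ids, region=region, side=side, segment=seg_ids)


# ---------------------------------------------------------------------------
# cylinders
# ---------------------------------------------------------------------------

def generate_cylinder(
    radius: float, length: float, resolution: float | None = None
) -> TriangleMesh:
    """Watertight capped cylinder along +z, base at z = 0, meters.

    ``resolution`` is the target edge length (default: 2*pi*R/24).
    """
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    edge = resolution or (2 * np.pi * radius / 24.0)
    n_circ = max(8, int(round(2 * np.pi * radius / edge)))
    n_ax = max(2, int(round(length / edge)))
    phi = np.linspace(0, 2 * np.pi, n_circ, endpoint=False)
    zs = np.linspace(0, length, n_ax + 1)
    ring = np.column_stack([radius * np.cos(phi), radius * np.sin(phi)])
    verts = [np.column_stack([ring, np.full(n_circ, z)]) for z in zs]
    verts = np.vstack(verts)
    faces = []
    for a in range(n_ax):
        base0, base1 = a * n_circ, (a + 1) * n_circ
        for i in range(n_circ):
            j = (i + 1) % n_circ
            faces.append([base0 + i, base0 + j, base1 + i])
            faces.append([base0 + j, base1 + j, base1 + i])
    c_bot = len(verts)
    c_top = len(verts) + 1
    verts = np.vstack([verts, [0, 0, 0], [0, 0, length]])
    top0 = n_ax * n_circ
    for i in range(n_circ):
        j = (i + 1) % n_circ
        faces.append([i, c_bot, j])                    # bottom cap (faces -z)
        faces.append([top0 + i, top0 + j, c_top])      # top cap (faces +z)
    return TriangleMesh(verts, np.array(faces, dtype=np.int64))


# ---------------------------------------------------------------------------
# analytic narrowing
# ---------------------------------------------------------------------------

def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def apply_known_narrowing(
    mesh: TriangleMesh,
    labels: SegmentLabels,
    tree: AirwayTreeGraph,
    segment_ids,
    radial_scale: float,
    blend_fraction: float = 0.25,
) -> TriangleMesh:
    """Ground-truth bottleneck: scale a segment's cross-sections radially.

    Vertices assigned to the listed segments move toward the segment axis by
    ``radial_scale`` in the core of the segment, with smoothstep blends over
    ``blend_fraction`` of the length at both ends, so the surface stays
    watertight and the true diameter ratio in the core equals the scale.
    """
    if not 0 < radial_scale <= 1:
        raise ValueError("radial scale must lie in (0, 1]")
    segment_ids = set(
        int(s) for s in (segment_ids if np.iterable(segment_ids) else [segment_ids])
    )
    for sid in segment_ids:
        if sid < 0 or sid >= len(tree.segments):
            raise KeyError(f"unknown segment id {sid}")
    verts = mesh.vertices.copy()
    # nearest segment per vertex
    best_d = np.full(len(verts), np.inf)
    best_seg = np.zeros(len(verts), dtype=np.int64)
    for seg in tree.segments:
        d, _ = _segment_distance(verts, seg, seg.radius)
        closer = d < best_d
        best_d[closer] = d[closer]
        best_seg[closer] = seg.segment_id
    for sid in segment_ids:
        seg = tree.segments[sid]
        mask = best_seg == sid
        if not mask.any():
            continue
        rel = verts[mask] - seg.start
        s = rel @ seg.axis
        radial = rel - s[:, None] * seg.axis
        bl = blend_fraction * seg.length
        ramp_in = _smoothstep(s / bl)
        ramp_out = _smoothstep((seg.length - s) / bl)
        bump = np.minimum(ramp_in, ramp_out)
        factor = 1.0 - (1.0 - radial_scale) * bump
        # additive form: exact identity when factor == 1
        verts[mask] = verts[mask] + radial * (factor - 1.0)[:, None]
    return mesh.with_vertices(verts)
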