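"""Ray/segment vs. triangle-mesh intersection on a uniform grid.

A Möller–Trumbore primitive test runs inside an Amanatides–Woo 3D-DDA
traversal of a uniform grid binning the triangles, compiled with numba and
parallelized over rays.  The same kernel serves two clients:

* the shape-diameter function (unbounded rays, an excluded origin face and
  the "fake intersection" normal filter), and
* the particle tracker (finite segments, first wall hit in ``t in [0, 1]``).
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

__all__ = ["TriangleGrid", "first_hits"]


@njit(cache=True, inline="always")
def _ray_tri(ox, oy, oz, dx, dy, dz, tri):
    """Möller–Trumbore; returns t (or inf) and barycentric validity."""
    e1x = tri[1, 0] - tri[0, 0]
    e1y = tri[1, 1] - tri[0, 1]
    e1z = tri[1, 2] - tri[0, 2]
    e2x = tri[2, 0] - tri[0, 0]
    e2y = tri[2, 1] - tri[0, 1]
    e2z = tri[2, 2] - tri[0, 2]
    px = dy * e2z - dz * e2y
    py = dz * e2x - dx * e2z
    pz = dx * e2y - dy * e2x
    det = e1x * px + e1y * py + e1z * pz
    if -1e-300 < det < 1e-300:
        return np.inf
    inv = 1.0 / det
    tx = ox - tri[0, 0]
    ty = oy - tri[0, 1]
    tz = oz - tri[0, 2]
    u = (tx * px + ty * py + tz * pz) * inv
    if u < -1e-9 or u > 1.0 + 1e-9:
        return np.inf
    qx = ty * e1z - tz * e1y
    qy = tz * e1x - tx * e1z
    qz = tx * e1y - ty * e1x
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < -1e-9 or u + v > 1.0 + 1e-9:
        return np.inf
    return (e2x * qx + e2y * qy + e2z * qz) * inv


@njit(cache=True, parallel=True)
def _traverse(
    origins, dirs, t_lo, t_hi,
    exclude, ref_normals, use_filter,
    tris, tri_normals,
    lo, inv_cell, ncell, cell_start, cell_tris,
):
    n = origins.shape[0]
    out_t = np.full(n, np.inf)
    out_f = np.full(n, -1, dtype=np.int64)
    nx, ny, nz = ncell[0], ncell[1], ncell[2]
    for r in prange(n):
        ox, oy, oz = origins[r, 0], origins[r, 1], origins[r, 2]
        dx, dy, dz = dirs[r, 0], dirs[r, 1], dirs[r, 2]
        # clip the ray to the grid box [lo, lo + ncell/inv_cell]
        tmin = t_lo
        tmax = t_hi[r]
        for a in range(3):
            o = origins[r, a]
            d = dirs[r, a]
            b0 = lo[a]
            b1 = lo[a] + ncell[a] / inv_cell[a]
            if abs(d) < 1e-300:
                if o < b0 or o > b1:
                    tmin = np.inf
                    break
            else:
                t0 = (b0 - o) / d
                t1 = (b1 - o) / d
                if t0 > t1:
                    t0, t1 = t1, t0
                if t0 > tmin:
                    tmin = t0
                if t1 < tmax:
                    tmax = t1
        if tmin > tmax or tmin == np.inf:
            continue
        # entry voxel
        eps = 1e-12
        px = ox + dx * (tmin + eps)
        py = oy + dy * (tmin + eps)
        pz = oz + dz * (tmin + eps)
        ix = int((px - lo[0]) * inv_cell[0])
        iy = int((py - lo[1]) * inv_cell[1])
        iz = int((pz - lo[2]) * inv_cell[2])
        if ix < 0: ix = 0
        if iy < 0: iy = 0
        if iz < 0: iz = 0
        if ix >= nx: ix = nx - 1
        if iy >= ny: iy = ny - 1
        if iz >= nz: iz = nz - 1
        stepx = 1 if dx > 0 else -1
        stepy = 1 if dy > 0 else -1
        stepz = 1 if dz > 0 else -1
        big = 1e300
        tdx = abs(1.0 / (dx * inv_cell[0])) if dx != 0 else big
        tdy = abs(1.0 / (dy * inv_cell[1])) if dy != 0 else big
        tdz = abs(1.0 / (dz * inv_cell[2])) if dz != 0 else big
        nextx = lo[0] + (ix + (1 if stepx > 0 else 0)) / inv_cell[0]
        nexty = lo[1] + (iy + (1 if stepy > 0 else 0)) / inv_cell[1]
        nextz = lo[2] + (iz + (1 if stepz > 0 else 0)) / inv_cell[2]
        tmx = (nextx - ox) / dx if dx != 0 else big
        tmy = (nexty - oy) / dy if dy != 0 else big
        tmz = (nextz - oz) / dz if dz != 0 else big
        best_t = np.inf
        best_f = -1
        t_exit = tmin
        while True:
            cell = (ix * ny + iy) * nz + iz
            s0 = cell_start[cell]
            s1 = cell_start[cell + 1]
            # exit t of this voxel
            t_exit = tmx if tmx < tmy else tmy
            if tmz < t_exit:
                t_exit = tmz
            for s in range(s0, s1):
                f = cell_tris[s]
                if f == exclude[r]:
                    continue
                if use_filter:
                    dp = (
                        tri_normals[f, 0] * ref_normals[r, 0]
                        + tri_normals[f, 1] * ref_normals[r, 1]
                        + tri_normals[f, 2] * ref_normals[r, 2]
                    )
                    if dp > 0.0:
                        continue
                t = _ray_tri(ox, oy, oz, dx, dy, dz, tris[f])
                if t_lo < t <= t_hi[r] and t < best_t:
                    best_t = t
                    best_f = f
            if best_t <= t_exit + 1e-12:
                break
            # step to next voxel
            if tmx < tmy:
                if tmx < tmz:
                    ix += stepx
                    tmx += tdx
                    if ix < 0 or ix >= nx:
                        break
                else:
                    iz += stepz
                    tmz += tdz
                    if iz < 0 or iz >= nz:
                        break
            else:
                if tmy < tmz:
                    iy += stepy
                    tmy += tdy
                    if iy < 0 or iy >= ny:
                        break
                else:
                    iz += stepz
                    tmz += tdz
                    if iz < 0 or iz >= nz:
                        break
            if t_exit > tmax:
                break
        if best_f >= 0:
            out_t[r] = best_t
            out_f[r] = best_f
    return out_t, out_f


class TriangleGrid:
    """Uniform-grid spatial index over the triangles of a mesh."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray,
                 cells_per_axis: int | None = None):
        vertices = np.asarray(vertices, float)
        faces = np.asarray(faces, np.int64)
        self.tris = np.ascontiguousarray(vertices[faces])
        cr = np.cross(
            self.tris[:, 1] - self.tris[:, 0], self.tris[:, 2] - self.tris[:, 0]
        )
        self.tri_normals = np.ascontiguousarray(
            cr / np.maximum(np.linalg.norm(cr, axis=1, keepdims=True), 1e-300)
        )
        m = len(faces)
        lo = self.tris.reshape(-1, 3).min(axis=0)
        hi = self.tris.reshape(-1, 3).max(axis=0)
        span = np.maximum(hi - lo, 1e-12)
        if cells_per_axis is None:
            cells_per_axis = int(np.clip(np.cbrt(m / 2.0), 4, 96))
        pad = 1e-9 * span.max() + 1e-300
        lo = lo - pad
        span = span + 2 * pad
        self.lo = lo
        self.ncell = np.full(3, cells_per_axis, dtype=np.int64)
        self.inv_cell = self.ncell / span
        # bin triangle AABBs into cells
        tmin = self.tris.min(axis=1)
        tmax = self.tris.max(axis=1)
        i0 = np.clip(((tmin - lo) * self.inv_cell).astype(np.int64), 0,
                     self.ncell - 1)
        i1 = np.clip(((tmax - lo) * self.inv_cell).astype(np.int64), 0,
                     self.ncell - 1)
        counts = (i1 - i0 + 1).prod(axis=1)
        total = int(counts.sum())
        cell_ids = np.empty(total, dtype=np.int64)
        tri_ids = np.empty(total, dtype=np.int64)
        pos = 0
        ny, nz = int(self.ncell[1]), int(self.ncell[2])
        for f in range(m):
            for ix in range(i0[f, 0], i1[f, 0] + 1):
                for iy in range(i0[f, 1], i1[f, 1] + 1):
                    for iz in range(i0[f, 2], i1[f, 2] + 1):
                        cell_ids[pos] = (ix * ny + iy) * nz + iz
                        tri_ids[pos] = f
                        pos += 1
        order = np.argsort(cell_ids, kind="stable")
        cell_ids, tri_ids = cell_ids[order], tri_ids[order]
        ncells = int(self.ncell.prod())
        self.cell_start = np.zeros(ncells + 1, dtype=np.int64)
        np.add.at(self.cell_start, cell_ids + 1, 1)
        np.cumsum(self.cell_start, out=self.cell_start)
        self.cell_tris = tri_ids

    def cast(
        self,
        origins: np.ndarray,
        directions: np.ndarray,
        t_min: float = 1e-9,
        t_max: np.ndarray | float = np.inf,
        exclude_face: np.ndarray | None = None,
        reject_normals: np.ndarray | None = None,
    ):
        """First hit per ray: (t, face); inf/-1 for misses.

        ``reject_normals`` (per-ray reference direction) discards any hit on
        a face whose geometric normal has positive dot product with it.
        Directions need not be unit length: ``t`` is in direction units, so
        segment queries pass the segment vector with ``t_max = 1``.
        """
        origins = np.ascontiguousarray(np.atleast_2d(origins), dtype=float)
        directions = np.ascontiguousarray(np.atleast_2d(directions), dtype=float)
        n = len(origins)
        if exclude_face is None:
            exclude = np.full(n, -1, dtype=np.int64)
        else:
            exclude = np.ascontiguousarray(exclude_face, dtype=np.int64)
        use_filter = reject_normals is not None
        ref = (
            np.ascontiguousarray(reject_normals, dtype=float)
            if use_filter
            else np.zeros((1, 3))
        )
        if np.isscalar(t_max):
            t_hi = np.full(n, float(t_max))
        else:
            t_hi = np.ascontiguousarray(t_max, dtype=float)
        return _traverse(
            origins, directions, t_min, t_hi,
            exclude, ref, use_filter,
            self.tris, self.tri_normals,
            self.lo, self.inv_cell, self.ncell,
            self.cell_start, self.cell_tris,
        )


def first_hits(
    origins: np.ndarray,
    directions: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    *,
    t_min: float = 1e-9,
    t_max: np.ndarray | float = np.inf,
    exclude_face: np.ndarray | None = None,
    reject_normals: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One-shot convenience wrapper building a :class:`TriangleGrid`."""
    grid = TriangleGrid(vertices, faces)
    return grid.cast(
        origins,
        directions,
        t_min=t_min,
        t_max=t_max,
        exclude_face=exclude_face,
        reject_normals=reject_normals,
    )
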