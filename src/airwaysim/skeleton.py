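"""Centerline extraction from a contracted mesh.

Once constrained Laplacian contraction has driven a closed airway surface to
(numerically) zero volume, the surviving triangulation is collapsed edge by
edge — shortest edge first, so the centerline drifts minimally — until no
triangles remain ("surgery connectivity").  The resulting 1D graph is then
simplified by merging chains of nearby degree-2 nodes, after which a binary
airway tree has only junction nodes (degree 3) and tips (degree 1).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .contraction import ContractionState
from .mesh import enclosed_volume

__all__ = ["Skeleton", "extract_skeleton", "merge_adjacent_nodes"]


@dataclass
class Skeleton:
    """1D curve skeleton: node positions, undirected edges and the map from
    every original surface vertex to the skeleton node it collapsed into."""

    nodes: np.ndarray          # (k, 3)
    edges: np.ndarray          # (e, 2) node index pairs
    vertex_map: np.ndarray     # (n_original,) -> node index

    def degrees(self) -> np.ndarray:
        d = np.zeros(len(self.nodes), dtype=np.int64)
        for a, b in self.edges:
            d[a] += 1
            d[b] += 1
        return d


class _Collapser:
    """Union-find edge collapse with a lazy shortest-edge heap."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        n = len(vertices)
        self.parent = np.arange(n)
        self.pos = vertices.copy()
        self.count = np.ones(n)          # how many originals merged in
        self.version = np.zeros(n, dtype=np.int64)
        self.adj: list[set[int]] = [set() for _ in range(n)]
        for f in faces:
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                if a != b:
                    self.adj[a].add(int(b))
                    self.adj[b].add(int(a))
        self.heap: list = []
        seen = set()
        for a in range(n):
            for b in self.adj[a]:
                if a < b:
                    seen.add((a, b))
        for a, b in seen:
            self._push(a, b)

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return int(a)

    def _push(self, a: int, b: int) -> None:
        d = float(np.linalg.norm(self.pos[a] - self.pos[b]))
        heapq.heappush(self.heap, (d, a, b, self.version[a], self.version[b]))

    def _in_triangle(self, a: int, b: int) -> bool:
        return len(self.adj[a] & self.adj[b]) > 0

    def run(self) -> None:
        """Collapse triangle edges (shortest first) until none remain."""
        while self.heap:
            d, a, b, va, vb = heapq.heappop(self.heap)
            if (
                self.parent[a] != a
                or self.parent[b] != b
                or self.version[a] != va
                or self.version[b] != vb
                or b not in self.adj[a]
            ):
                continue
            if not self._in_triangle(a, b):
                continue
            # merge b into a at the count-weighted centroid
            ca, cb = self.count[a], self.count[b]
            self.pos[a] = (ca * self.pos[a] + cb * self.pos[b]) / (ca + cb)
            self.count[a] = ca + cb
            self.parent[b] = a
            self.adj[a].discard(b)
            self.adj[b].discard(a)
            for c in self.adj[b]:
                self.adj[c].discard(b)
                if c != a:
                    self.adj[c].add(a)
                    self.adj[a].add(c)
            self.adj[b] = set()
            self.version[a] += 1
            for c in self.adj[a]:
                self._push(a, c)


def extract_skeleton(
    state: ContractionState, volume_threshold: float = 1e-7
) -> Skeleton:
    """Collapse a contracted mesh into its curve skeleton.

    Requires the contraction to have reached a normalized enclosed volume
    below ``volume_threshold``; otherwise the collapse would cut corners of
    still-inflated geometry and the centerline would be meaningless.
    """
    mesh = state.mesh
    v_norm = abs(enclosed_volume(mesh)) / abs(state.volume_history[0])
    if v_norm >= volume_threshold:
        raise ValueError(
            f"mesh volume ratio {v_norm:.2e} >= {volume_threshold:.0e}; "
            "run more contraction iterations before skeletonization"
        )
    coll = _Collapser(mesh.vertices, mesh.faces)
    coll.run()

    roots = np.array([coll.find(i) for i in range(mesh.n_vertices)])
    alive = np.unique(roots)
    remap = {int(r): i for i, r in enumerate(alive)}
    nodes = coll.pos[alive]
    edges = set()
    for a in alive:
        for b in coll.adj[a]:
            rb = coll.find(int(b))
            if rb != a:
                edges.add((remap[min(int(a), rb)], remap[max(int(a), rb)]))
    vertex_map = np.array([remap[int(r)] for r in roots])
    return Skeleton(
        nodes=nodes,
        edges=np.array(sorted(edges), dtype=np.int64).reshape(-1, 2),
        vertex_map=vertex_map,
    )


def merge_adjacent_nodes(skel: Skeleton, tolerance: float) -> Skeleton:
    """Merge chains of degree-2 nodes separated by less than ``tolerance``.

    Nodes merge to the centroid of the original nodes they absorb; the
    vertex map is composed accordingly.  ``tolerance = 0`` is a no-op.
    """
    n = len(skel.nodes)
    parent = np.arange(n)
    pos = skel.nodes.copy()
    count = np.ones(n)
    adj: list[set[int]] = [set() for _ in range(n)]
    for a, b in skel.edges:
        adj[a].add(int(b))
        adj[b].add(int(a))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return int(a)

    changed = True
    while changed:
        changed = False
        for a in range(n):
            if parent[a] != a:
                continue
            for b in list(adj[a]):
                if parent[b] != b or b == a:
                    continue
                if len(adj[a]) != 2 and len(adj[b]) != 2:
                    continue
                if np.linalg.norm(pos[a] - pos[b]) >= tolerance:
                    continue
                ca, cb = count[a], count[b]
                pos[a] = (ca * pos[a] + cb * pos[b]) / (ca + cb)
                count[a] = ca + cb
                parent[b] = a
                adj[a].discard(b)
                adj[b].discard(a)
                for c in adj[b]:
                    adj[c].discard(b)
                    if c != a:
                        adj[c].add(a)
                        adj[a].add(c)
                adj[b] = set()
                changed = True
                break

    roots = np.array([find(i) for i in range(n)])
    alive = np.unique(roots)
    remap = {int(r): i for i, r in enumerate(alive)}
    nodes = pos[alive]
    edges = set()
    for a in alive:
        for b in adj[a]:
            rb = find(int(b))
            if rb != a:
                edges.add((remap[min(int(a), rb)], remap[max(int(a), rb)]))
    vmap = np.array([remap[find(int(m))] for m in skel.vertex_map])
    return Skeleton(
        nodes=nodes,
        edges=np.array(sorted(edges), dtype=np.int64).reshape(-1, 2),
        vertex_map=vmap,
    )
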