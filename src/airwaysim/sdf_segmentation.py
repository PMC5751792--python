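"""Shape-diameter function (SDF), its post-processing, mesh segmentation by
Gaussian-mixture soft clustering plus graph-cut hard clustering, and the
SDF-based narrowing ratio.

The SDF assigns each face an estimate of the local wall-to-wall diameter:
a cone of rays is cast from the face centroid around the inward normal,
intersections on the near side of the surface ("fake" hits whose outward
normal agrees with the origin face's) are discarded, ray lengths outside
one standard deviation of the median are trimmed, and the rest are averaged
with inverse-angle weights.  Summed over a region, the SDF tracks the local
mean lumen diameter, so the ratio of the sums after vs. before a deformation
is the narrowing ratio the bronchoconstriction loop drives to its target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from sklearn.mixture import GaussianMixture

from .mesh import TriangleMesh, centroids, face_normals
from .raycast import first_hits

__all__ = [
    "SdfField",
    "ClusterModel",
    "SegmentLabels",
    "raw_sdf",
    "postprocess_sdf",
    "soft_cluster",
    "hard_cluster",
    "segmentation_energy",
    "narrowing_ratio",
]

#: offset added to ray angles before inverting, so the axis ray has finite weight
ANGLE_DELTA = 1e-3
DEFAULT_CONE_HALF_ANGLE = np.pi / 3.0
DEFAULT_N_RAYS = 25


@dataclass
class SdfField:
    """Per-face local-diameter field in mesh units (raw) and processed forms."""

    raw: np.ndarray
    missing: np.ndarray
    smoothed: np.ndarray | None = None
    normalized: np.ndarray | None = None
    params: dict = field(default_factory=dict)


@dataclass
class ClusterModel:
    """Gaussian mixture over normalized SDF values with face posteriors."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    posteriors: np.ndarray  # (n_faces, k)
    epsilon: float = 1e-5

    @property
    def k(self) -> int:
        return len(self.means)


@dataclass
class SegmentLabels:
    """Per-face segmentation: cluster id, plus optional anatomical annotation.

    ``region`` holds strings such as ``upper``, ``gen3``, ``outlet``;
    ``side`` holds ``left``/``right``/""; both are filled by the synthetic
    airway generator and consumed by the deposition accounting.
    """

    labels: np.ndarray
    region: np.ndarray | None = None
    side: np.ndarray | None = None
    segment: np.ndarray | None = None  # airway-tree segment id per face


# ---------------------------------------------------------------------------
# raw SDF
# ---------------------------------------------------------------------------

def _cone_directions(n_rays: int, half_angle: float) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic low-discrepancy directions on a spherical cap around +z.

    Fibonacci-spiral sampling: uniform in cos(theta) over the cap, golden-
    angle azimuths.  Returns unit vectors and their angles from the axis.
    """
    i = np.arange(n_rays)
    cos_t = 1.0 - (i + 0.5) / n_rays * (1.0 - np.cos(half_angle))
    theta = np.arccos(np.clip(cos_t, -1, 1))
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    sin_t = np.sin(theta)
    dirs = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    return dirs, theta


def _frames(axes: np.ndarray) -> np.ndarray:
    """Orthonormal frame (m, 3, 3) with the given unit vectors as z-columns."""
    helper = np.zeros_like(axes)
    helper[:, 0] = 1.0
    flip = np.abs(axes[:, 0]) > 0.9
    helper[flip] = [0.0, 1.0, 0.0]
    x = np.cross(helper, axes)
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    y = np.cross(axes, x)
    return np.stack([x, y, axes], axis=2)


def raw_sdf(
    mesh: TriangleMesh,
    cone_half_angle: float = DEFAULT_CONE_HALF_ANGLE,
    n_rays: int = DEFAULT_N_RAYS,
    face_subset: np.ndarray | None = None,
    target_mesh: TriangleMesh | None = None,
) -> SdfField:
    """Ray-sampled local diameter per face (or per ``face_subset`` face).

    Rays leave each face centroid inside a cone around the inward normal;
    hits whose outward normal agrees with the origin normal are rejected;
    kept lengths are trimmed to one standard deviation around the median
    and averaged with weights ``1 / (angle_from_axis + delta)``.

    ``target_mesh`` restricts the surfaces rays may hit (defaults to the
    probed mesh itself); faces with no valid ray get ``raw = nan`` and are
    flagged in ``missing``.
    """
    target = mesh if target_mesh is None else target_mesh
    normals = face_normals(mesh)
    cents = centroids(mesh)
    if face_subset is None:
        face_subset = np.arange(mesh.n_faces)
    face_subset = np.asarray(face_subset, dtype=np.int64)
    n_sub = len(face_subset)

    canon, angles = _cone_directions(n_rays, cone_half_angle)
    axes = -normals[face_subset]  # inward
    frames = _frames(axes)
    dirs = np.einsum("mab,rb->mra", frames, canon).reshape(-1, 3)
    origins = np.repeat(cents[face_subset], n_rays, axis=0)
    same_mesh = target_mesh is None or target_mesh is mesh
    exclude = (
        np.repeat(face_subset, n_rays) if same_mesh else None
    )
    t, _hit_face = first_hits(
        origins,
        dirs,
        target.vertices,
        target.faces,
        exclude_face=exclude,
        reject_normals=np.repeat(normals[face_subset], n_rays, axis=0),
    )
    t = t.reshape(n_sub, n_rays)
    w = 1.0 / (np.tile(angles, (n_sub, 1)) + ANGLE_DELTA)

    raw = np.full(n_sub, np.nan)
    valid = np.isfinite(t)
    for i in range(n_sub):
        ti, wi = t[i][valid[i]], w[i][valid[i]]
        if len(ti) == 0:
            continue
        med = np.median(ti)
        sd = ti.std()
        keep = np.abs(ti - med) <= sd + 1e-300
        raw[i] = np.average(ti[keep], weights=wi[keep])

    full_raw = np.full(mesh.n_faces, np.nan)
    full_raw[face_subset] = raw
    missing = np.isnan(full_raw)
    if face_subset is not None and len(face_subset) < mesh.n_faces:
        out = np.ones(mesh.n_faces, dtype=bool)
        out[face_subset] = np.isnan(raw)
        missing = out
    return SdfField(
        raw=full_raw,
        missing=missing,
        params={
            "cone_half_angle": cone_half_angle,
            "n_rays": n_rays,
            "face_subset": face_subset,
        },
    )


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def _face_adjacency_lists(mesh: TriangleMesh, faces: np.ndarray) -> list[list[int]]:
    pairs = mesh.face_adjacency()
    in_set = np.zeros(mesh.n_faces, bool)
    in_set[faces] = True
    adj: dict[int, list[int]] = {int(f): [] for f in faces}
    for a, b in pairs:
        if in_set[a] and in_set[b]:
            adj[int(a)].append(int(b))
            adj[int(b)].append(int(a))
    return adj


def postprocess_sdf(fieldv: SdfField, mesh: TriangleMesh) -> SdfField:
    """Fill missing faces, bilateral-smooth, min-max normalize to [0, 1].

    Window size is ``w = floor(sqrt(|F|/2000)) + 1`` levels of breadth-first
    face adjacency, the spatial bandwidth is ``w/2`` (in hops) and the range
    bandwidth per face is the RMS difference of the field over its window.
    A constant field cannot be normalized; it maps to all-zero with a warning.
    """
    sub = np.asarray(fieldv.params.get("face_subset", np.arange(mesh.n_faces)))
    raw = fieldv.raw.copy()
    adj = _face_adjacency_lists(mesh, sub)

    missing = [f for f in sub if np.isnan(raw[f])]
    if len(missing) == len(sub):
        raise ValueError("all SDF values are missing; nothing to post-process")
    # iterative neighbor fill (edge-adjacent average)
    while missing:
        still = []
        for f in missing:
            vals = [raw[g] for g in adj[f] if not np.isnan(raw[g])]
            if vals:
                raw[f] = float(np.mean(vals))
            else:
                still.append(f)
        if len(still) == len(missing):
            raw[still] = np.nanmean(raw[sub])
            break
        missing = still

    n_f = len(sub)
    w = int(np.floor(np.sqrt(n_f / 2000.0))) + 1
    sigma_s = w / 2.0

    smoothed = raw.copy()
    for f in sub:
        # breadth-first neighborhood to depth w with hop distances
        hops = {int(f): 0}
        frontier = [int(f)]
        for depth in range(1, w + 1):
            nxt = []
            for g in frontier:
                for h in adj[g]:
                    if h not in hops:
                        hops[h] = depth
                        nxt.append(h)
            frontier = nxt
        idx = np.fromiter(hops.keys(), dtype=np.int64)
        hop = np.fromiter(hops.values(), dtype=np.float64)
        diffs = raw[idx] - raw[f]
        sigma_r = np.sqrt(np.mean(diffs**2))
        ws = np.exp(-(hop**2) / (2.0 * sigma_s**2))
        if sigma_r > 0:
            ws = ws * np.exp(-(diffs**2) / (2.0 * sigma_r**2))
        smoothed[f] = np.sum(ws * raw[idx]) / np.sum(ws)

    vals = smoothed[sub]
    lo, hi = float(vals.min()), float(vals.max())
    normalized = np.full_like(smoothed, np.nan)
    if hi - lo < 1e-300:
        warnings.warn(
            "constant SDF field: normalization degenerate, mapped to zeros",
            RuntimeWarning,
            stacklevel=2,
        )
        normalized[sub] = 0.0
    else:
        normalized[sub] = (vals - lo) / (hi - lo)
    return SdfField(
        raw=raw,
        missing=np.zeros_like(fieldv.missing),
        smoothed=smoothed,
        normalized=normalized,
        params={**fieldv.params, "w": w, "sigma_s": sigma_s},
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def soft_cluster(
    fieldv: SdfField,
    k: int = 4,
    n_restarts: int = 5,
    seed: int = 0,
    epsilon: float = 1e-5,
) -> ClusterModel:
    """Fit a k-component Gaussian mixture to the normalized SDF values.

    k-means++ initialization, best of ``n_restarts`` EM runs by likelihood.
    """
    if fieldv.normalized is None:
        raise ValueError("run postprocess_sdf first (normalized values required)")
    sub = np.asarray(fieldv.params.get("face_subset"))
    x = fieldv.normalized[sub].reshape(-1, 1)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(np.unique(x)):
        raise ValueError(f"k={k} exceeds the number of distinct SDF values")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="diag",
        n_init=n_restarts,
        init_params="k-means++",
        random_state=seed,
        reg_covar=1e-9,
    ).fit(x)
    post = np.zeros((len(fieldv.raw), k))
    post[sub] = gm.predict_proba(x)
    return ClusterModel(
        means=gm.means_.ravel(),
        variances=gm.covariances_.ravel(),
        weights=gm.weights_.ravel(),
        posteriors=post,
        epsilon=epsilon,
    )


def _dihedral_costs(mesh: TriangleMesh):
    """Adjacent face pairs with smoothness costs -log(theta/pi) * w_concavity."""
    pairs = mesh.face_adjacency()
    n = face_normals(mesh)
    c = centroids(mesh)
    nf, ng = n[pairs[:, 0]], n[pairs[:, 1]]
    cosang = np.clip(np.einsum("ij,ij->i", nf, ng), -1.0, 1.0)
    theta = np.pi - np.arccos(cosang)  # pi = coplanar
    # convex edge: the neighbor's centroid lies below f's tangent plane
    convex = np.einsum("ij,ij->i", c[pairs[:, 1]] - c[pairs[:, 0]], nf) < 0.0
    wconc = np.where(convex, 0.1, 1.0)
    cost = -np.log(np.maximum(theta, 1e-12) / np.pi) * wconc
    return pairs, np.maximum(cost, 0.0)


def segmentation_energy(
    labels: np.ndarray,
    unary: np.ndarray,
    pairs: np.ndarray,
    pair_cost: np.ndarray,
    lam: float,
) -> float:
    """E = sum_f e1(f, x_f) + lambda * sum_{f,g} e2(x_f, x_g)."""
    e1 = unary[np.arange(len(labels)), labels].sum()
    diff = labels[pairs[:, 0]] != labels[pairs[:, 1]]
    return float(e1 + lam * pair_cost[diff].sum())


def _binary_cut(unary: np.ndarray, pairs, cost, lam, faces_idx) -> np.ndarray:
    """Exact s-t minimum cut for a 2-label energy (labels 0/1)."""
    g = nx.DiGraph()
    s, t = "s", "t"
    for f in faces_idx:
        g.add_edge(s, f, capacity=float(unary[f, 1]))  # pay u(f,0) if on source side
        g.add_edge(f, t, capacity=float(unary[f, 0]))
    for (a, b), c in zip(pairs, cost):
        cap = float(lam * c)
        if cap > 0:
            g.add_edge(int(a), int(b), capacity=cap)
            g.add_edge(int(b), int(a), capacity=cap)
    _val, (src_side, _snk) = nx.minimum_cut(g, s, t)
    labels = np.ones(unary.shape[0], dtype=np.int64)
    for f in src_side:
        if f != s:
            labels[f] = 0
    return labels


def _alpha_expansion(unary, pairs, cost, lam, init):
    """Alpha-expansion for k > 2; the pair cost is Potts-like (label free)."""
    labels = init.copy()
    nlab = unary.shape[1]
    improved = True
    current = segmentation_energy(labels, unary, pairs, cost, lam)
    while improved:
        improved = False
        for alpha in range(nlab):
            g = nx.DiGraph()
            s, t = "s", "t"
            for f in range(unary.shape[0]):
                keep = np.inf if labels[f] == alpha else unary[f, labels[f]]
                g.add_edge(s, f, capacity=float(unary[f, alpha]))
                g.add_edge(f, t, capacity=float(min(keep, 1e30)))
            for idx, (a, b) in enumerate(pairs):
                c = float(lam * cost[idx])
                if c <= 0:
                    continue
                a, b = int(a), int(b)
                if labels[a] == labels[b]:
                    g.add_edge(a, b, capacity=c)
                    g.add_edge(b, a, capacity=c)
                else:
                    aux = ("aux", idx)
                    g.add_edge(a, aux, capacity=c)
                    g.add_edge(aux, a, capacity=c)
                    g.add_edge(b, aux, capacity=c)
                    g.add_edge(aux, b, capacity=c)
                    g.add_edge(aux, t, capacity=c)
            _val, (src_side, _snk) = nx.minimum_cut(g, s, t)
            snk_side = set(range(unary.shape[0])) - {
                f for f in src_side if isinstance(f, (int, np.integer))
            }
            cand = labels.copy()
            cand[list(snk_side)] = alpha
            e = segmentation_energy(cand, unary, pairs, cost, lam)
            if e < current - 1e-12:
                labels, current, improved = cand, e, True
    return labels


def hard_cluster(
    model: ClusterModel,
    mesh: TriangleMesh,
    lam: float = 0.26,
) -> SegmentLabels:
    """Final segmentation minimizing posterior unaries + dihedral smoothness.

    ``lam = 0`` decouples the energy: each face takes its argmax posterior.
    k = 2 is solved by an exact s-t minimum cut; larger k by alpha-expansion
    (each move an s-t cut) started from the argmax labeling.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("smoothness lambda must lie in [0, 1]")
    unary = -np.log(np.maximum(model.posteriors, model.epsilon))
    init = model.posteriors.argmax(axis=1)
    if lam == 0.0 or model.k == 1:
        return SegmentLabels(labels=init)
    pairs, cost = _dihedral_costs(mesh)
    if model.k == 2:
        labels = _binary_cut(unary, pairs, cost, lam, range(mesh.n_faces))
    else:
        labels = _alpha_expansion(unary, pairs, cost, lam, init)
    e_init = segmentation_energy(init, unary, pairs, cost, lam)
    e_cut = segmentation_energy(labels, unary, pairs, cost, lam)
    if e_cut > e_init:  # safeguard: never worse than the unary-only labeling
        labels = init
    return SegmentLabels(labels=labels)


# ---------------------------------------------------------------------------
# narrowing ratio
# ---------------------------------------------------------------------------

def narrowing_ratio(
    field_before: SdfField,
    field_after: SdfField,
    face_subset: np.ndarray | None = None,
) -> float:
    """r^t = sum(SDF after) / sum(SDF before) over the processed faces.

    Raw (un-normalized) values are used; min-max rescaling would make the
    ratio meaningless.  1.0 = unchanged, 0.5 = 50 % narrowing.
    """
    if face_subset is None:
        face_subset = np.asarray(field_before.params.get("face_subset"))
    face_subset = np.asarray(face_subset, dtype=np.int64)
    before = np.nansum(field_before.raw[face_subset])
    after = np.nansum(field_after.raw[face_subset])
    if before <= 0:
        raise ZeroDivisionError("sum of SDF values before narrowing is zero")
    return float(after / before)
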