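# Methods

This note documents the models implemented in `airwaysim`, the parameters
that matter, the numerical choices behind them, and what the synthetic
fixtures do and do not represent.

## Scope and intent

The package models two things and their interaction:

1. **Obstruction geometry.** Given a watertight triangle surface of an
   airway tree, a selected region is narrowed to a prescribed
   shape-diameter ratio by constrained Laplacian contraction
   (bronchoconstriction simulation), with skeletonization of the whole tree
   as the degenerate full-contraction case and bilateral/Taubin smoothing
   to blend the deformed region back into the intact surface.
2. **Aerosol deposition.** Spherical particles are tracked through a
   prescribed flow field over the labelled surface with a stick boundary
   condition, and deposition is reported per airway generation and per
   lung section.

A turbulent CFD solution of the airway flow is deliberately out of scope:
the tracker consumes any velocity-at-point contract, and ships an analytic
Poiseuille tree field plus an import path for externally computed fields
(trilinear interpolation of legacy-VTK structured-points samples).
Deposition numbers therefore characterize the laminar, idealized-geometry
regime, not any specific patient.

## Mesh operators

The cotangent ("curvature-flow") Laplacian has off-diagonal entries
`w_ij = cot a_ij + cot b_ij` on edges — the two angles facing the edge in
its adjacent triangles — and diagonal minus the row sum, so constants are
annihilated. Cotangents are clamped at 1e8 in magnitude: contraction drives
triangles toward degeneracy, and unbounded weights destroy the solve.
Boundary edges of non-watertight inputs use their single available angle.
Enclosed volume is the signed divergence-theorem sum and requires a closed
mesh. All coordinates are in meters; fixtures state their physical scale.

## Constrained contraction

One iteration solves, per coordinate,

    minimize  ||W_L L V||^2  +  sum_j W_H_j^2 ||V_j - V_a_j||^2

via the sparse normal equations `(W_L^2 L^T L + diag(W_H^2)) V' =
diag(W_H^2) V_a`, with one factorization shared by x, y, z. Between
iterations the Laplacian is recomputed on the deformed mesh, the
contraction weight is amplified, and each anchor weight is rescaled by
`sqrt(A_i^0 / A_i^t)` (initial over current one-ring area of vertex i), so
collapsing neighborhoods are progressively released. The one-ring area is
used for `A_i^t` deliberately: it is the natural discrete vertex area in
this scheme. Collapsed one-rings are floored at 1e-12 of their initial
area.

**Unit-area normalization.** The default starting balance
`W_L = k omega sqrt(A)` (k = 1e-3, A the model's mean face area) against
unit anchors is not dimensionless: cotangent weights are scale-invariant
while `sqrt(A)` carries length units, so the same constants that visibly
contract a coarse millimeter-scale mesh do nothing at meter scale or at
finer resolutions. The bronchoconstriction driver therefore rescales its
working coordinates so the model's mean face area is 1 (the narrowing
ratio and all angles are invariant under this), making the behavior of
k = 1e-3 independent of units and mesh resolution. Outputs are scaled
back, and the whole procedure is exactly scale-equivariant (the tests
verify bit-level agreement across a 1024-fold change of scale).

**Termination.** Two policies exist. For skeletonization the loop runs
until `|enclosed volume| / |initial volume| < 1e-7` (the threshold is
interpreted as a normalized volume, since an absolute volume would be
unit-dependent), with a hard iteration cap; volume-increasing steps —
possible once triangles degenerate — are rejected and retried with a
larger contraction weight, which keeps the recorded volume history
non-increasing. For bronchoconstriction the loop runs while the narrowing
ratio exceeds `r + e` within the iteration budget `t`.

## Bronchoconstriction

The narrowing loop follows six steps per run: initialize
`W_L = k omega sqrt(A)`, `W_H = I`; solve; update weights; recompute the
Laplacian; recompute the narrowing ratio; repeat while `r_t > r + e`.
Only vertices of the selected face region enter the linear system. The
region's one-ring boundary is softly anchored with a 1e3 multiplier, and
all vertices outside the region are excluded from the system entirely, so
they move exactly zero — the seam is then treated by the smoothing stage.

**Amplification schedule (`s_L`).** The per-iteration amplification factor
of `W_L` is a free parameter of the scheme; no canonical value exists for
ratio-targeted narrowing, and a fixed geometric schedule (e.g. doubling)
either stalls far from the target or overshoots it depending on the mesh,
because the ratio response to `W_L` is a sharp knee spanning several
decades. The default schedule (`s_L="auto"`) is therefore a monotone line
search: each iteration grows `W_L` aggressively while the ratio has not
moved, and log-bisects between the last two candidates as soon as a
candidate solve would land below `r - e`. A candidate is accepted when it
makes material progress without overshooting; accepted iterations count
toward the budget `t`, and the number of candidate solves per iteration is
capped (default 12). A numeric `s_L` reproduces the plain open-loop
geometric schedule. With the default schedule the two-branch fixture
reaches a 0.49–0.52 ratio against a 0.5 target across tube radii of
1–5 mm and a range of mesh resolutions.

**Abnormality modulation.** An optional per-vertex diagonal
`W_V = omega + (1 - omega)/2 * sin(kappa d)` (or any user function of d)
modulates `W_L`, where `d` is the graph-geodesic distance from the region
boundary. Since `d` is in mesh units, the sinusoid argument is rescaled by
a wavenumber `kappa` (default `2 pi / max(d)`) so the spatial period of the
waviness does not depend on resolution or units. Weights are floored at
1e-6 (the sinusoid goes non-positive for omega < 1/3).

## Shape-diameter function

Per face, 25 deterministic Fibonacci-spiral rays are cast in a cone of
half-angle 60 degrees around the inward normal (the ray set is identical
in every face's local frame, so the field is reproducible run to run).
Hits whose outward surface normal points the same way as the origin face's
normal are discarded as fake near-side intersections; remaining lengths
are trimmed to one standard deviation around their median and averaged
with weights `1/(angle + 1e-3)`, the offset keeping the axis ray finite.
Ray casting is a Möller–Trumbore test inside a numba-compiled
Amanatides–Woo uniform-grid traversal; the same kernel does the particle
wall-collision queries.

Post-processing fills faces with no valid rays from their edge-adjacent
neighbors, applies one pass of bilateral smoothing over breadth-first face
neighborhoods of depth `w = floor(sqrt(|F|/2000)) + 1` (spatial bandwidth
`w/2` in hops, per-face range bandwidth the RMS field difference over the
window) and min–max normalizes to [0, 1]. A constant field cannot be
normalized and maps to zeros with a warning.

The narrowing ratio is `sum(raw SDF after) / sum(raw SDF before)` over the
processed faces — raw values, because min–max normalization would destroy
the physical meaning of the ratio. During the narrowing loop the SDF is
recomputed only on the processed region (rays cast against the region
submesh), which is both faster and closer to a local lumen measure.

## Segmentation

Soft clustering fits a k-component Gaussian mixture to the normalized SDF
values (k-means++ initialization, best of n restarts, fixed seed =
reproducible model). Hard clustering minimizes posterior negative
log-likelihood unaries (floored at epsilon) plus a dihedral smoothness
term `-log(theta/pi)` on adjacent faces with unequal labels, weighted 1
for concave and 0.1 for convex edges. k = 2 is solved exactly by an s-t
minimum cut; k > 2 by alpha-expansion (each move an s-t cut, valid here
because the pair cost is label-independent and hence metric), started from
the argmax labeling and never returning anything worse than it.
Defaults k = 4, lambda = 0.26, epsilon = 1e-5 are implementation choices
exposed as configuration.

## Smoothing

Bilateral normal filtering builds a k-nearest-neighbor adjacency over face
centroids (k = 8), weights it by Gaussians on centroid distance
(bandwidth: mean neighbor distance) and on normal difference (0.35),
row-normalizes, applies it `zeta` times (default 1) to the normal stack
and renormalizes. Vertices then move by the mean, over incident faces, of
the filtered normal times its point-plane residual, with centroids
refreshed every iteration; a flat patch with exact normals is a fixed
point. Taubin smoothing alternates +0.33 / -0.34 uniform-Laplacian steps
(pass-band: volume preserved to ~1 % where plain Laplacian flow shrinks)
and holds an explicit anchor set fixed — the stable-area boundary when
cleaning a narrowing seam.

## Flow fields

The Poiseuille tree field assigns each straight segment a fully developed
parabolic profile matching its flowrate (centerline velocity twice the
mean, zero at the wall), blending linearly within one radius of segment
ends so the field is continuous across junctions; points in no segment get
zero velocity and an out-of-domain flag. Flowrates are split at junctions
either equally or by Poiseuille conductance `R^4 / L` (default), so
narrowing a branch starves it — the mechanism behind the unilateral
obstruction study. Fluid defaults are air at 20 °C (rho = 1.204 kg/m^3,
mu = 1.81e-5 Pa s). Conservation at junctions is exact to rounding and
asserted at 1e-10.

## Particle transport

Forces: Schiller–Naumann drag
`C_D = (24/Re)(1 + 0.15 Re^0.687)` for Re <= 1000, 0.44 above, pure Stokes
below Re = 1e-8 (so the Stokes identity `C_D Re / 24 -> 1` holds exactly
in the limit); gravity + buoyancy along -z (on by default, g = 9.81);
optionally Stokes rotational drag `T = pi mu d^3 (Omega_F - omega)` with
`Omega_F` half the local vorticity — rotation is off by default and does
not feed back into translation.

The single-particle stepper sub-steps a 4-stage Runge–Kutta integrator at
`tau_P / 5`. Because `tau_P = rho_P d_P^2 / (18 mu_F)` is 3.1 us for a
1 um particle, explicit substepping at the 0.5 ms transport step would
need hundreds of substeps, so above a substep cap (24) the stepper
switches to an exponential integrator that is exact for Stokes drag in a
frozen flow. The ensemble tracker goes further: it freezes the flow over
each 0.5 ms step (particles move < 1 mm per step, well under the 4–8 mm
segment radii over which the field varies) and always applies the
exponential velocity/position update, which makes 5000-particle sweeps
across 1–30 um run in seconds per case. Wall collision is a swept
segment-triangle query per step through the same spatial grid as the SDF;
the first hit sticks the particle at the contact point with the region
label of the hit face, outlet-cap hits escape, and terminal states are
one-way. Counts satisfy deposited + escaped + in-flight = injected
exactly, by construction and by assertion.

Injection follows the nominal study conditions: particles enter uniformly
over a disc spanning 80 % of the tracheal radius, at the local mean air
speed along the inlet normal, staggered uniformly over a 0.75 ms period;
the nominal ensemble is 54,000 particles of 10 um and 1000 kg/m^3 tracked
for 2.16 s at dt = 0.5 ms with a 12.6 L/min inlet flowrate. Validation
runs use 5000 particles per cell, which keeps the full diameter x density
grid within minutes while leaving Monte-Carlo noise on section fractions
near 0.3 %; the tracker exits early once every particle is terminal, which
on this geometry happens well before 2.16 s. The same seed produces the
same injection across parameter values (common random numbers), so
diameter, density and obstruction comparisons are paired rather than
independent — directional comparisons then reflect physics, not sampling
noise.

## Synthetic airway tree

`generate_tree` emulates a central-airway model: a trachea (16 mm
diameter, length three diameters) splitting symmetrically with a 35 degree
half-angle, child/parent diameter ratio `2^(-1/3)` (Weibel-like), lengths
three diameters, branching planes rotating 90 degrees per generation,
down to `generations` bifurcation levels (`2^G` outlets; the 5-level
default gives 63 segments). The surface is the zero level set of the union
of per-segment capsule distance fields on a regular grid (default pitch:
root diameter / 16), triangulated by marching cubes — watertight across
junctions by construction, which both the SDF and the particle tracker
rely on. Faces are labelled by nearest segment, with two conventions:
junction collars (within one parent radius of a segment's proximal end)
belong to the parent airway, so the carina saddle counts as trachea/upper
airways, and faces beyond the distal end of a terminal segment form its
outlet cap. Left/right follows the generation-1 ancestor.

What this fixture does *not* emulate: patient-specific asymmetry (beyond
an optional diameter/angle skew), cartilage ring texture, the mouth-throat
above the trachea (where much of the real coarse-particle impaction
happens — upper-airway fractions here are accordingly small), curved
centerlines, and turbulence. Passing trend checks on it demonstrates that
the transport model responds directionally (size, density, obstruction) as
expected from impaction/sedimentation physics, not that absolute
deposition fractions match any patient.

`apply_known_narrowing` provides analytic ground truth for the ratio
machinery: radial scaling of a segment's cross-sections about its axis
with smoothstep blends over 25 % of the length at both ends, so the core
diameter ratio equals the requested scale exactly and the mesh topology
(hence watertightness) is untouched.

## Reproduction protocols

`airwaysim.studies` holds the canonical experiments: narrowing-ratio
recovery on the two-branch ~2 mm fixture with the default parameter set
(r=0.5, e=0.05, t=8, omega=0.8); skeletonization of a two-level tree to
below the 1e-7 volume ratio with a {degree-1, degree-3} merged skeleton;
and the deposition runs. `scripts/acceptance.py` reruns the narrowing
recovery from scratch and writes the achieved narrowing percentage.

## Known limitations

- Laminar analytic flow only; no turbulent dispersion, no secondary flows
  at bifurcations beyond what profile blending induces.
- No Brownian motion: sub-micron particles see only drag and gravity, so
  diffusional deposition is absent.
- One-way coupling; dilute suspension assumed.
- Alpha-expansion uses a generic max-flow (networkx); fine for the mesh
  sizes used here, not tuned for very large segmentations.
- The skeleton is a graph-geodesic centerline; no radius profile is
  attached to it.
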