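"""Canonical end-to-end study protocols.

These functions wire the synthetic fixtures, the geometry pipeline and the
particle tracker into the standard experiments the package is validated
against: narrowing-ratio recovery on a two-branch airway segment,
skeletonization of a bifurcating tree, and the particle diameter / density /
obstruction sweeps on the 5-generation tree.  Both the test suite and the
reproduction script call these, so the protocols live in one place.
"""

from __future__ import annotations

import collections

import numpy as np

from .bronchoconstriction import NarrowingSpec, simulate_bronchoconstriction
from .contraction import VolumeThreshold, contract_iterative
from .flow import poiseuille_tree_field, split_flow
from .skeleton import extract_skeleton, merge_adjacent_nodes
from .synthetic import TreeSpec, generate_tree
from .transport import InjectionSpec, deposition_fractions, track

__all__ = [
    "narrowing_recovery",
    "skeletonization_study",
    "deposition_run",
]

#: inlet flowrate of the unobstructed study condition: 12.6 L/min
INLET_FLOWRATE = 12.6 / 60000.0  # m^3/s


def narrowing_recovery(
    seed: int = 0,
    r: float = 0.5,
    e: float = 0.05,
    t: int = 8,
    omega: float = 0.8,
) -> dict:
    """Constrict the two ~2 mm child branches of a small airway segment.

    Fixture: trachea + one bifurcation (root diameter 5 mm, children
    1.98 mm radius); the processed region is every face of the two child
    tubes.  Returns the achieved shape-diameter narrowing ratio.
    """
    mesh, labels, _tree = generate_tree(
        TreeSpec(generations=1, root_diameter=0.005, seed=seed)
    )
    region = np.flatnonzero(labels.region == "gen1")
    spec = NarrowingSpec(r=r, e=e, t=t, omega=omega, region=region)
    res = simulate_bronchoconstriction(mesh, spec)
    return {
        "achieved_ratio": res.achieved_ratio,
        "narrowing_percent": 100.0 * res.achieved_ratio,
        "converged": res.converged,
        "iterations": res.iterations,
        "n_region_faces": int(len(region)),
    }


def skeletonization_study(seed: int = 0, volume_threshold: float = 1e-7) -> dict:
    """Contract a two-level tree to (numerically) zero volume and extract
    its centerline; report the volume ratio reached and node degrees."""
    mesh, _labels, _tree = generate_tree(
        TreeSpec(generations=2, root_diameter=0.008, mesh_resolution=0.0008,
                 seed=seed)
    )
    state = contract_iterative(
        mesh, stop=VolumeThreshold(volume_threshold), hard_cap=80
    )
    out = {
        "iterations": state.iteration,
        "converged": state.converged,
        "volume_ratio": abs(state.volume_history[-1])
        / abs(state.volume_history[0]),
        "n_vertices": mesh.n_vertices,
    }
    if state.converged:
        skel = merge_adjacent_nodes(
            extract_skeleton(state, volume_threshold), np.inf
        )
        out["degrees"] = collections.Counter(skel.degrees().tolist())
        out["n_nodes"] = len(skel.nodes)
    return out


def deposition_run(
    mesh,
    labels,
    tree,
    diameter: float = 10e-6,
    density: float = 1000.0,
    count: int = 5000,
    seed: int = 0,
    duration: float = 2.16,
    dt: float = 5e-4,
    inlet_flowrate: float = INLET_FLOWRATE,
):
    """Track one monodisperse ensemble through a labelled tree.

    The flow is the resistance-split Poiseuille tree field; particles enter
    on a disc spanning 80 % of the tracheal radius with the local mean air
    speed.  The same seed yields identical injections across parameter
    values, so paired comparisons (diameter, density, obstruction) see the
    same particles.
    """
    tree = split_flow(tree, inlet_flowrate, rule="resistance")
    flow = poiseuille_tree_field(tree)
    root = tree.root
    u_inlet = root.flowrate / (np.pi * root.radius**2)
    spec = InjectionSpec(
        count=count,
        period=0.75e-3,
        center=root.start + 0.05 * root.length * root.axis,
        normal=root.axis,
        radius=0.8 * root.radius,
        speed=u_inlet,
        diameter=diameter,
        density=density,
        seed=seed,
    )
    result = track(spec, flow, mesh, labels, duration=duration, dt=dt)
    return deposition_fractions(result, labels)
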