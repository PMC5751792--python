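"""Particle drag, time integration, tracking and deposition accounting."""

import math

import numpy as np
import pytest

from airwaysim.flow import UniformField, uniform_field
from airwaysim.synthetic import generate_cylinder
from airwaysim.sdf_segmentation import SegmentLabels
from airwaysim.transport import (
    InjectionSpec,
    ParticleState,
    STATUS_DEPOSITED,
    STATUS_ESCAPED,
    STATUS_INFLIGHT,
    TrackResult,
    deposition_fractions,
    drag,
    relaxation_time,
    step,
    track,
)

AIR = uniform_field([0, 0, 0])


def particle(**kw):
    kw.setdefault("x", np.zeros(3))
    kw.setdefault("u", np.zeros(3))
    kw.setdefault("d", 10e-6)
    kw.setdefault("rho", 1000.0)
    return ParticleState(**kw)


class TestDrag:
    def test_no_slip_no_force(self):
        f, re, _cd = drag([0, 0, 0], particle(), AIR.rho, AIR.mu)
        assert np.allclose(f, 0.0)
        assert re == 0.0

    def test_reynolds_number_value(self):
        # d = 10 um, |slip| = 1 m/s, air: Re = 1.204e-5 / 1.81e-5
        _f, re, _cd = drag([1.0, 0, 0], particle(), AIR.rho, AIR.mu)
        assert re == pytest.approx(1.204e-5 / 1.81e-5, rel=1e-12)
        assert re == pytest.approx(0.665, abs=0.001)

    def test_stokes_limit_recovered(self):
        _f, re, cd = drag([1e-9, 0, 0], particle(), AIR.rho, AIR.mu)
        assert cd * re / 24.0 == pytest.approx(1.0, rel=1e-9)

    def test_stokes_force_closed_form(self):
        slip = 1e-9
        f, _re, _cd = drag([slip, 0, 0], particle(), AIR.rho, AIR.mu)
        assert f[0] == pytest.approx(3 * np.pi * AIR.mu * 10e-6 * slip, rel=1e-9)

    def test_derived_quantities(self):
        p = particle()
        assert p.mass == pytest.approx(1000.0 * (10e-6) ** 3 * np.pi / 6)
        assert p.inertia == pytest.approx(0.1 * p.mass * (10e-6) ** 2)
        assert p.cross_section == pytest.approx((10e-6) ** 2 * np.pi / 4)


class TestStep:
    def test_zero_dt_unchanged(self):
        p = particle(u=np.array([1.0, 0, 0]))
        out = step(p, AIR, 0.0)
        assert np.array_equal(out.x, p.x)
        assert np.array_equal(out.u, p.u)

    def test_stokes_relaxation_closed_form(self):
        """RK4 at dt = tau/20 matches the exponential to 1e-6 relative."""
        u0 = 1e-8  # Re < 1e-8: pure Stokes drag
        tau = relaxation_time(10e-6, 1000.0, AIR.mu)
        flow = UniformField(np.array([u0, 0, 0]))
        cur = particle()
        for _ in range(20):
            cur = step(cur, flow, tau / 20.0, gravity=False)
        exact = u0 * (1.0 - math.exp(-1.0))
        assert abs(cur.u[0] - exact) / exact < 1e-6

    def test_settling_velocity(self):
        tau = relaxation_time(10e-6, 1000.0, AIR.mu)
        cur = particle()
        for _ in range(200):
            cur = step(cur, AIR, tau / 2.0, gravity=True)
        v_expected = (1000.0 - AIR.rho) * 9.81 * (10e-6) ** 2 / (18 * AIR.mu)
        assert v_expected == pytest.approx(3.0e-3, abs=1e-4)
        assert -cur.u[2] == pytest.approx(v_expected, rel=0.01)

    def test_stiff_path_settling(self):
        """1 um particle: exponential integrator reaches terminal velocity."""
        cur = particle(d=1e-6)
        cur = step(cur, AIR, 0.1, gravity=True)  # >> tau ~ 3 us
        v_expected = (1000.0 - AIR.rho) * 9.81 * (1e-6) ** 2 / (18 * AIR.mu)
        assert -cur.u[2] == pytest.approx(v_expected, rel=1e-6)

    def test_terminal_state_is_frozen(self):
        p = particle(status="deposited")
        out = step(p, AIR, 1.0)
        assert np.array_equal(out.x, p.x)

    def test_rotation_relaxes_to_half_vorticity(self):
        flow = UniformField(np.array([1.0, 0, 0]))
        p = particle(omega=np.array([5.0, 0, 0]))
        out = step(p, flow, 1.0, rotation=True)
        assert np.allclose(out.omega, 0.0, atol=1e-6)  # uniform: vorticity 0


@pytest.fixture(scope="module")
def tube():
    mesh = generate_cylinder(0.005, 0.05)
    region = np.array(["wall"] * mesh.n_faces, dtype=object)
    side = np.array([""] * mesh.n_faces, dtype=object)
    labels = SegmentLabels(labels=np.zeros(mesh.n_faces, dtype=int),
                           region=region, side=side)
    return mesh, labels


class TestTracking:

    def test_dead_end_tube_deposits_everything(self, tube):
        mesh, labels = tube
        flow = uniform_field([0, 0, 1.0])
        spec = InjectionSpec(count=50, period=0.0, center=[0, 0, 0.01],
                             normal=[0, 0, 1.0], radius=0.003, speed=1.0,
                             seed=2)
        res = track(spec, flow, mesh, labels, duration=0.5, dt=1e-3)
        assert (res.status == STATUS_DEPOSITED).all()

    def test_axis_particle_escapes_wall_particle_deposits(self, tube):
        mesh, labels = tube
        out_region = labels.region.copy()
        # top cap acts as the outlet
        from airwaysim.mesh import centroids

        c = centroids(mesh)
        out_region[c[:, 2] > 0.0499] = "outlet"
        labels2 = SegmentLabels(labels=labels.labels, region=out_region,
                                side=labels.side)
        flow = uniform_field([0, 0, 1.0])
        spec = InjectionSpec(count=2, period=0.0, center=[0, 0, 0.01],
                             normal=[0, 0, 1.0], radius=0.0, speed=1.0, seed=0)
        res = track(spec, flow, mesh, labels2, duration=0.5, dt=1e-3)
        assert (res.status == STATUS_ESCAPED).all()  # axial -> outlet cap
        spec_wall = InjectionSpec(count=2, period=0.0, center=[0, 0, 0.01],
                                  normal=[1.0, 0, 0], radius=0.0, speed=1.0,
                                  seed=0)
        res2 = track(spec_wall, uniform_field([1.0, 0, 0]), mesh, labels2,
                     duration=0.5, dt=1e-3)
        assert (res2.status == STATUS_DEPOSITED).all()

    def test_count_conservation_exact(self, tree5):
        mesh, labels, tree = tree5
        from airwaysim.flow import poiseuille_tree_field, split_flow

        tr = split_flow(tree, 2.1e-4)
        flow = poiseuille_tree_field(tr)
        root = tr.root
        spec = InjectionSpec(count=400, center=root.start + 0.002 * root.axis,
                             normal=root.axis, radius=0.8 * root.radius,
                             speed=1.0, seed=3)
        res = track(spec, flow, mesh, labels, duration=0.2, dt=5e-4)
        n_dep = (res.status == STATUS_DEPOSITED).sum()
        n_esc = (res.status == STATUS_ESCAPED).sum()
        n_fly = (res.status == STATUS_INFLIGHT).sum()
        assert n_dep + n_esc + n_fly == spec.count

    def test_determinism_bit_identical(self, tube):
        mesh, labels = tube
        flow = uniform_field([0, 0, 1.0])
        spec = InjectionSpec(count=30, period=1e-3, center=[0, 0, 0.01],
                             normal=[0, 0, 1.0], radius=0.003, speed=1.0,
                             seed=11)
        a = track(spec, flow, mesh, labels, duration=0.3, dt=1e-3)
        b = track(spec, flow, mesh, labels, duration=0.3, dt=1e-3)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.status, b.status)
        assert np.array_equal(a.hit_face, b.hit_face)


class TestDepositionReport:
    def test_hand_built_outcomes(self):
        regions = np.array(
            ["upper", "gen1", "gen2", "outlet"], dtype=object
        )
        sides = np.array(["", "left", "right", ""], dtype=object)
        labels = SegmentLabels(labels=np.arange(4), region=regions, side=sides)
        status = np.array([
            STATUS_DEPOSITED, STATUS_DEPOSITED, STATUS_DEPOSITED,
            STATUS_ESCAPED, STATUS_INFLIGHT, STATUS_INFLIGHT,
            STATUS_DEPOSITED, STATUS_DEPOSITED, STATUS_DEPOSITED,
            STATUS_ESCAPED,
        ])
        region = np.array([
            "upper", "gen1", "gen2", None, None, None,
            "gen1", "gen1", "gen2", None,
        ], dtype=object)
        hit_face = np.array([0, 1, 2, -1, -1, -1, 1, 1, 2, -1])
        res = TrackResult(
            positions=np.zeros((10, 3)), velocities=np.zeros((10, 3)),
            status=status, region=region, hit_face=hit_face,
            injected=10, rejected=0, time=1.0,
        )
        rep = deposition_fractions(res, labels)
        assert rep.section_counts == {
            "upper": 1, "left": 3, "right": 2, "outlet": 2,
            "in-flight": 2, "unlabelled": 0,
        }
        assert rep.generation_counts["gen1"] == 3
        assert rep.generation_counts["gen2"] == 2
        assert rep.section_fractions["left"] == pytest.approx(0.3)

    def test_fractions_partition_to_one(self):
        labels = SegmentLabels(labels=np.zeros(1, dtype=int),
                               region=np.array(["gen1"], dtype=object),
                               side=np.array(["left"], dtype=object))
        status = np.array([STATUS_INFLIGHT] * 5)
        res = TrackResult(
            positions=np.zeros((5, 3)), velocities=np.zeros((5, 3)),
            status=status, region=np.array([None] * 5, dtype=object),
            hit_face=np.full(5, -1), injected=5, rejected=0, time=1.0,
        )
        rep = deposition_fractions(res, labels)
        assert sum(rep.section_fractions.values()) == pytest.approx(1.0,
                                                                    abs=1e-12)
        assert rep.section_counts["in-flight"] == 5
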