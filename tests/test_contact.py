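"""Elastic-foundation contact: force decomposition, Newton pairs, friction
cone, dissipation and the von Mises equivalent-stress map."""

import numpy as np
import pytest

from tmjload.contact import (
    ContactBottomOut,
    ContactForceRecord,
    ContactParams,
    ContactPatchState,
    equivalent_stress_field,
    evaluate_contact,
    evaluate_dental_contact,
    joint_mean_force,
    total_compartment_force,
)
from tmjload.materials import (
    MooneyRivlinMaterial,
    PronyBranchState,
    PronySeries,
    mooney_rivlin_uniaxial_stress,
)

MAT = MooneyRivlinMaterial()
PRONY = PronySeries()
PARAMS = ContactParams(layer_thickness=6.0)


def _state(pen, rate=None, slip=None, areas=None, normals=None):
    pen = np.atleast_1d(np.asarray(pen, dtype=float))
    n = len(pen)
    return ContactPatchState(
        penetration=pen,
        penetration_rate=np.zeros(n) if rate is None else np.atleast_1d(rate),
        slip_velocity=np.zeros((n, 3)) if slip is None else np.atleast_2d(slip),
        areas=np.ones(n) if areas is None else np.atleast_1d(areas),
        normals=np.tile([0.0, 0.0, 1.0], (n, 1)) if normals is None else np.atleast_2d(normals),
    )


def _random_state(rng, n=20):
    normals = rng.standard_normal((n, 3))
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return ContactPatchState(
        penetration=rng.uniform(0.0, 3.0, n) * (rng.random(n) > 0.3),
        penetration_rate=rng.uniform(-50.0, 50.0, n),
        slip_velocity=rng.uniform(-20.0, 20.0, (n, 3)),
        areas=rng.uniform(0.2, 4.0, n),
        normals=normals,
    )


class TestEvaluateContact:
    def test_no_penetration_no_force(self):
        rec = evaluate_contact(_state(np.zeros(5), rate=np.full(5, 10.0)),
                               MAT, PRONY, PARAMS)
        assert np.all(rec.total == 0.0)
        assert total_compartment_force(rec) == 0.0

    def test_single_element_closed_form(self):
        """delta/h = 0.05 at zero rates: elastic force = A * |sigma_MR(0.95)|,
        damping and friction zero."""
        area = 2.5
        rec = evaluate_contact(_state([0.3], areas=[area]), MAT, PRONY, PARAMS)
        expected = area * abs(mooney_rivlin_uniaxial_stress(0.95, MAT)) / 1e6
        assert np.linalg.norm(rec.elastic.sum(axis=0)) == pytest.approx(expected, abs=1e-9)
        assert np.all(rec.damping == 0.0)
        assert np.all(rec.friction == 0.0)

    def test_frictionless_limit(self, rng):
        params = ContactParams(layer_thickness=6.0, friction_coefficient=0.0)
        for _ in range(20):
            rec = evaluate_contact(_random_state(rng), MAT, PRONY, params)
            assert np.all(rec.friction == 0.0)

    def test_bottom_out_raises(self):
        with pytest.raises(ContactBottomOut):
            evaluate_contact(_state([6.0]), MAT, PRONY, PARAMS)

    def test_elastic_force_monotone_in_penetration(self):
        depths = np.linspace(0.0, 4.0, 50)
        mags = [np.linalg.norm(
            evaluate_contact(_state([d]), MAT, PRONY, PARAMS).elastic.sum(axis=0))
            for d in depths]
        assert np.all(np.diff(mags) >= 0)

    def test_newton_third_law_and_friction_cone(self, rng):
        """On >= 1000 randomized element states: the counterpart record is the
        exact negation, and |friction| <= mu |normal| per element."""
        mu = 0.15
        params = ContactParams(layer_thickness=6.0, friction_coefficient=mu)
        checked = 0
        for _ in range(60):
            state = _random_state(rng, n=25)
            rec = evaluate_contact(state, MAT, PRONY, params)
            counter = rec.counterpart()
            np.testing.assert_allclose(rec.total + counter.total, 0.0, atol=1e-10)
            normal_mag = np.abs(np.sum((rec.elastic + rec.damping) * state.normals, axis=1))
            friction_mag = np.linalg.norm(rec.friction, axis=1)
            assert np.all(friction_mag <= mu * normal_mag + 1e-12)
            checked += len(state)
        assert checked >= 1000

    def test_damping_dissipates_over_closed_cycle(self):
        """Closed penetration cycle with mu = 0: net work done by the damping
        forces is non-positive."""
        params = ContactParams(layer_thickness=6.0, friction_coefficient=0.0)
        hist = PronyBranchState(PRONY, 1)
        dt = 1e-4
        t = np.arange(0, 0.02, dt)
        depth = 1.0 + 0.5 * np.sin(2 * np.pi * t / 0.01)
        work = 0.0
        prev = depth[0]
        hist.prime(np.array([prev / 6.0]))
        for d in depth[1:]:
            rate = (d - prev) / dt
            rec = evaluate_contact(_state([d], rate=[rate]), MAT, PRONY, params,
                                   history=hist, dt=dt)
            f_damp = float(rec.damping.sum(axis=0)[2])
            work += f_damp * (-(d - prev))     # force on counter-body along +z
            prev = d
        assert work <= 1e-12


class TestDentalContact:
    def test_separated_teeth_no_force(self):
        rec = evaluate_dental_contact(-0.1, 0.0, np.zeros(3), [0, 0, -1.0], PARAMS)
        assert len(rec.elastic) == 0

    def test_engaged_normal_force(self):
        rec = evaluate_dental_contact(0.05, 0.0, np.zeros(3), [0, 0, -1.0], PARAMS,
                                      side="right")
        f = rec.total.sum(axis=0)
        assert f[2] == pytest.approx(-PARAMS.dental_stiffness * 0.05)
        assert rec.compartment == "dental"

    def test_cusp_interlock_capped_by_slope(self):
        offset = np.array([0.0, 2.0, 0.0])     # large tangential offset
        rec = evaluate_dental_contact(0.01, 0.0, np.zeros(3), [0, 0, -1.0], PARAMS,
                                      tangential_offset=offset)
        f = rec.elastic.sum(axis=0)
        f_n = PARAMS.dental_stiffness * 0.01
        tangential = np.hypot(f[0], f[1])
        assert tangential <= PARAMS.cusp_slope * f_n + 1e-9


class TestCombination:
    def test_tangential_cancellation(self):
        rec = ContactForceRecord(
            elastic=np.array([[1.0, 0.0, 2.0], [-1.0, 0.0, 2.0]]),
            damping=np.zeros((2, 3)), friction=np.zeros((2, 3)),
            normal_pressure=np.zeros(2), tangential_traction=np.zeros(2))
        assert total_compartment_force(rec) == pytest.approx(4.0)

    def test_empty_record_zero(self):
        assert total_compartment_force(ContactForceRecord.empty()) == 0.0

    def test_matches_brute_force_sum(self, rng):
        for mode in ("vector", "magnitude"):
            e, d, f = rng.standard_normal((3, 30, 3))
            rec = ContactForceRecord(elastic=e, damping=d, friction=f,
                                     normal_pressure=np.zeros(30),
                                     tangential_traction=np.zeros(30))
            total = e + d + f
            expected = (np.linalg.norm(total.sum(axis=0)) if mode == "vector"
                        else np.linalg.norm(total, axis=1).sum())
            assert total_compartment_force(rec, mode) == pytest.approx(expected)

    def test_joint_mean(self):
        assert joint_mean_force(10.0, 20.0) == 15.0
        assert joint_mean_force(7.0, 7.0) == 7.0
        assert joint_mean_force(0.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            joint_mean_force(-1.0, 5.0)


class TestEquivalentStress:
    def _record(self, p, tau):
        return ContactForceRecord(
            elastic=np.zeros((1, 3)), damping=np.zeros((1, 3)),
            friction=np.zeros((1, 3)),
            normal_pressure=np.array([p]), tangential_traction=np.array([tau]))

    def test_uniaxial_case(self):
        assert equivalent_stress_field(self._record(1e5, 0.0))[0] == pytest.approx(1e5)

    def test_pure_shear_case(self):
        vm = equivalent_stress_field(self._record(0.0, 1e4))[0]
        assert vm == pytest.approx(np.sqrt(3) * 1e4)

    def test_hydrostatic_invariance(self):
        """sigma_vm of (p uniaxial + tau shear) from the (p, tau) reduction is
        unchanged when a hydrostatic part is added to the underlying tensor."""
        p, tau, hydro = 2e5, 5e4, 7e5
        s = np.diag([-p, 0.0, 0.0]).astype(float)
        s[0, 1] = s[1, 0] = tau
        for sig in (s, s + hydro * np.eye(3)):
            dev = sig - np.trace(sig) / 3.0 * np.eye(3)
            vm_tensor = np.sqrt(1.5 * np.sum(dev * dev))
            assert vm_tensor == pytest.approx(np.sqrt(p**2 + 3 * tau**2), rel=1e-12)
        assert equivalent_stress_field(self._record(p, tau))[0] == pytest.approx(
            np.sqrt(p**2 + 3 * tau**2))
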