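"""Rigid-mandible dynamics: activation envelopes, muscle wrenches, incisal
opening, determinism, mirror equivariance, timestep convergence and
integrator energy behaviour."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tmjload.analysis import PhaseWindow, window_mean
from tmjload.contact import ContactParams
from tmjload.dynamics import (
    ActivationProtocol,
    DynamicsParams,
    MuscleElement,
    RigidBodyState,
    activation,
    default_muscles,
    incisal_opening,
    muscle_forces,
    simulate_open_close,
)
from tmjload.geometry import (
    GeometryParams,
    ShorteningSpec,
    build_geometry,
    mirror_geometry,
    shorten_ramus,
)

PROTOCOL = ActivationProtocol()


class TestActivation:
    def test_bounds(self):
        for t in np.linspace(0, PROTOCOL.duration, 801):
            for role in ("opener", "closer"):
                a = activation(float(t), PROTOCOL, role)
                assert 0.0 <= a <= 1.0

    def test_opener_peaks_at_open_keyframes(self):
        grid = np.linspace(0, PROTOCOL.duration, 8001)
        vals = np.array([activation(float(t), PROTOCOL, "opener") for t in grid])
        assert activation(0.075, PROTOCOL, "opener") == pytest.approx(vals.max())
        assert activation(0.275, PROTOCOL, "opener") == pytest.approx(vals.max())
        # cycle repeat
        assert activation(0.075, PROTOCOL, "opener") == pytest.approx(
            activation(0.275, PROTOCOL, "opener"), abs=1e-9)

    def test_closer_peaks_at_approach_to_closure(self):
        grid = np.linspace(0, PROTOCOL.duration, 8001)
        vals = np.array([activation(float(t), PROTOCOL, "closer") for t in grid])
        assert activation(0.185, PROTOCOL, "closer") == pytest.approx(vals.max())
        assert activation(0.365, PROTOCOL, "closer") == pytest.approx(vals.max())
        # near-quiescent at the open keyframes
        assert activation(0.075, PROTOCOL, "closer") < 0.5 * vals.max()

    def test_out_of_range_time_rejected(self):
        with pytest.raises(ValueError):
            activation(-0.01, PROTOCOL, "opener")
        with pytest.raises(ValueError):
            activation(0.5, PROTOCOL, "closer")
        with pytest.raises(ValueError):
            activation(0.1, PROTOCOL, "chewer")


class TestMuscleForces:
    def test_zero_activation_zero_wrench(self, baseline_geometry):
        state = RigidBodyState(position=baseline_geometry.com,
                               quaternion=np.array([0, 0, 0, 1.0]))
        prot = ActivationProtocol(opener_gain=0.0, closer_gain=0.0, tonic=0.0)
        F, tq = muscle_forces(state, baseline_geometry,
                              default_muscles(baseline_geometry), 0.05, prot)
        np.testing.assert_allclose(F, 0.0, atol=1e-12)
        np.testing.assert_allclose(tq, 0.0, atol=1e-12)

    def test_single_muscle_full_activation_magnitude(self, baseline_geometry):
        g = baseline_geometry
        state = RigidBodyState(position=g.com, quaternion=np.array([0, 0, 0, 1.0]))
        m = MuscleElement("solo", "right", origin=[0, 0, 50.0],
                          insertion=[0, 0, -50.0], peak_force=80.0, role="opener")
        prot = ActivationProtocol(opener_gain=1.0)
        F, _ = muscle_forces(state, g, [m], 0.075, prot)   # opener at its peak
        assert np.linalg.norm(F) == pytest.approx(80.0)

    def test_degenerate_muscle_rejected(self, baseline_geometry):
        g = baseline_geometry
        state = RigidBodyState(position=g.com, quaternion=np.array([0, 0, 0, 1.0]))
        m = MuscleElement("bad", "right", origin=g.com + np.array([1.0, 2.0, 3.0]),
                          insertion=np.array([1.0, 2.0, 3.0]) + g.com,
                          peak_force=10.0, role="closer")
        with pytest.raises(ValueError, match="degenerate"):
            muscle_forces(state, g, [m], 0.0, PROTOCOL)

    def test_mirrored_system_gives_mirrored_wrench(self, baseline_geometry):
        g = baseline_geometry
        gm = mirror_geometry(g)
        rot = Rotation.from_rotvec([0.1, 0.05, -0.03])
        rot_m = Rotation.from_rotvec([0.1, -0.05, 0.03])
        s = RigidBodyState(position=g.com + [1.0, 2.0, -1.0], quaternion=rot.as_quat())
        s_m = RigidBodyState(position=gm.com + [-1.0, 2.0, -1.0],
                             quaternion=rot_m.as_quat())
        F, tq = muscle_forces(s, g, default_muscles(g), 0.05, PROTOCOL)
        F_m, tq_m = muscle_forces(s_m, gm, default_muscles(gm), 0.05, PROTOCOL)
        np.testing.assert_allclose(F_m, F * np.array([-1, 1, 1]), atol=1e-9)
        np.testing.assert_allclose(tq_m, tq * np.array([1, -1, -1]), atol=1e-9)


class TestIncisalOpening:
    def test_closed_reference_pose_zero(self, baseline_geometry):
        state = RigidBodyState(position=baseline_geometry.com,
                               quaternion=np.array([0, 0, 0, 1.0]))
        assert incisal_opening(state, baseline_geometry) == 0.0

    def test_pure_inferior_translation(self, baseline_geometry):
        state = RigidBodyState(position=baseline_geometry.com + [0, 0, -10.0],
                               quaternion=np.array([0, 0, 0, 1.0]))
        assert incisal_opening(state, baseline_geometry) == pytest.approx(10.0)

    @pytest.mark.parametrize("theta", [0.05, 0.2, 0.4])
    def test_pure_hinge_rotation(self, baseline_geometry, theta):
        """Rotation about the intercondylar axis opens by 2 r sin(theta/2)."""
        g = baseline_geometry
        rot = Rotation.from_rotvec([-theta, 0, 0])
        state = RigidBodyState(position=rot.apply(g.com), quaternion=rot.as_quat())
        inc = g.landmarks["incisal_point"]
        r = np.hypot(inc[1], inc[2])        # distance from the x-axis
        assert incisal_opening(state, g) == pytest.approx(
            2 * r * np.sin(theta / 2), rel=1e-9)


class TestSimulation:
    def test_determinism_bitwise(self, fast_geometry):
        a = simulate_open_close(fast_geometry, dt=1e-4, duration=0.1)
        b = simulate_open_close(fast_geometry, dt=1e-4, duration=0.1)
        for side in ("right", "left"):
            np.testing.assert_array_equal(a.mean_force[side], b.mean_force[side])
        np.testing.assert_array_equal(a.opening_mm, b.opening_mm)

    def test_mirror_equivariance(self, fast_geometry):
        """Reflecting the whole system (an 8 mm right shortening becomes an
        8 mm left shortening) swaps the left/right force traces."""
        g_right = shorten_ramus(fast_geometry, ShorteningSpec("right", 8.0))
        g_mirror = mirror_geometry(g_right)
        a = simulate_open_close(g_right, dt=1e-4, duration=0.12)
        b = simulate_open_close(g_mirror, dt=1e-4, duration=0.12)
        assert np.abs(a.mean_force["right"] - b.mean_force["left"]).max() < 1e-6
        assert np.abs(a.mean_force["left"] - b.mean_force["right"]).max() < 1e-6

    def test_timestep_convergence_of_window_means(self, fast_geometry):
        """Halving the timestep changes the windowed mean forces by < 2%."""
        coarse = simulate_open_close(fast_geometry, dt=1e-4, duration=0.2)
        fine = simulate_open_close(fast_geometry, dt=5e-5, duration=0.2)
        for w in (PhaseWindow("open1", 70.0, 79.9), PhaseWindow("closed", 180.0, 189.9)):
            for side in ("right", "left"):
                a = window_mean(coarse.time_ms, coarse.mean_force[side], w)
                b = window_mean(fine.time_ms, fine.mean_force[side], w)
                assert abs(a - b) / max(a, b) < 0.02

    def test_loads_peak_open_and_dip_closed(self, baseline_result):
        """Condylar load is maximal around maximal opening and lower with the
        jaw closed in occlusion."""
        res = baseline_result
        open_w = window_mean(res.time_ms, res.mean_force["right"],
                             PhaseWindow("open", 270.0, 279.9))
        closed_w = window_mean(res.time_ms, res.mean_force["right"],
                               PhaseWindow("closed", 180.0, 189.9))
        assert open_w > closed_w

    def test_energy_drift_without_dissipation(self, fast_geometry):
        """Free oscillation with friction, damping and activation all off:
        mechanical energy drift stays below 5% of the peak kinetic energy
        (symplectic integrator sanity)."""
        g = fast_geometry
        rot = Rotation.from_rotvec([-0.08, 0, 0])
        start = RigidBodyState(position=rot.apply(g.com), quaternion=rot.as_quat())
        dp = DynamicsParams(gravity=0.0, passive_rot_damping=(0.0, 0.0, 0.0),
                            linear_damping=0.0, capsule_damping=0.0)
        cp = ContactParams(layer_thickness=g.params.stack_thickness,
                           damping_source="none", friction_coefficient=0.0,
                           dental_stiffness=0.0, dental_tangential_stiffness=0.0,
                           constant_damping=0.0)
        prot = ActivationProtocol(opener_gain=0.0, closer_gain=0.0)
        # negligible contact stiffness: the passive elements alone carry the
        # oscillation, so the recorded energy functional is exact
        mats = {"cartilage": __import__("tmjload").MooneyRivlinMaterial(C1=1e-3, C2=0.0)}
        dt = 2e-5
        res = simulate_open_close(g, mats, protocol=prot, dt=dt, duration=0.1,
                                  contact_params=cp, dynamics_params=dp,
                                  record_energy=True, initial_state=start)
        v = np.diff(res.positions, axis=0) / dt
        rots = Rotation.from_quat(res.quaternions)
        w = (rots[1:] * rots[:-1].inv()).as_rotvec() / dt
        inertia = np.array(g.params.mandible_inertia)
        ke = (0.5 * g.params.mandible_mass * np.sum(v**2, axis=1)
              + 0.5 * np.sum(w**2 * inertia, axis=1)) * 1e-6
        drift = res.energy.max() - res.energy.min()
        assert drift < 0.05 * ke.max()

    def test_invalid_timestep_rejected(self, fast_geometry):
        with pytest.raises(ValueError):
            simulate_open_close(fast_geometry, dt=0.0, duration=0.01)

    def test_quaternion_norm_validated(self):
        with pytest.raises(ValueError):
            RigidBodyState(position=np.zeros(3), quaternion=np.array([0, 0, 0, 1.1]))
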