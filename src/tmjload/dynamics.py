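"""Six-degree-of-freedom muscle-driven rigid-mandible dynamics.

The mandible is a rigid body suspended from the fixed skull through the two
TMJ contact stacks, dental contacts near closure, per-side capsule tethers,
and a passive rotational stiffness/damping wrench (passive elastic recoil
of the elevator muscles and joint capsules).  Twelve masticatory muscle
groups per side pull along straight origin->insertion lines with
activation envelopes that imitate two open-close cycles in 0.4 s: the
mouth is closed at 0, 185 and 365 ms and maximally open (30 mm incisal
opening after calibration) at 75 and 275 ms.

Integration is fixed-step semi-implicit (symplectic) Euler with body-frame
Euler equations for the rotation; the run is fully deterministic.

Units: mm, N, kg, s (accelerations therefore carry a factor 1000).
"""

from __future__ import annotations

import time as _time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .contact import (
    ContactParams,
    ContactPatchState,
    equivalent_stress_field,
    evaluate_contact,
    evaluate_dental_contact,
    joint_mean_force,
    total_compartment_force,
)
from .geometry import SIDES, MasticatoryGeometry
from .materials import MooneyRivlinMaterial, PronyBranchState, PronySeries

__all__ = [
    "MuscleElement",
    "ActivationProtocol",
    "RigidBodyState",
    "SimulationResult",
    "DynamicsParams",
    "SimulationDiverged",
    "activation",
    "muscle_forces",
    "simulate_open_close",
    "incisal_opening",
    "default_muscles",
    "calibrate_opener_gain",
]

OPENER = "opener"
CLOSER = "closer"


class SimulationDiverged(RuntimeError):
    """The state became non-finite or a contact bottomed out."""


@dataclass(frozen=True)
class MuscleElement:
    """One masticatory muscle group on one side.

    ``origin`` is skull-fixed, ``insertion`` mandible-fixed (closed-pose
    coordinates, mm); ``peak_force`` in N; ``role`` opener or closer.
    """

    name: str
    side: str
    origin: np.ndarray
    insertion: np.ndarray
    peak_force: float
    role: str

    def __post_init__(self) -> None:
        if self.peak_force <= 0:
            raise ValueError(f"peak force must be > 0 for {self.name}")
        if self.role not in (OPENER, CLOSER):
            raise ValueError(f"role must be opener or closer, got {self.role!r}")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "insertion", np.asarray(self.insertion, dtype=float))


def default_muscles(geom: MasticatoryGeometry) -> list[MuscleElement]:
    """The twelve named groups, bilaterally, from the geometry's table."""
    out = []
    for side in SIDES:
        for name, m in geom.muscles[side].items():
            out.append(MuscleElement(name=name, side=side, origin=m["origin"],
                                     insertion=m["insertion"], peak_force=m["peak"],
                                     role=m["role"]))
    return out


@dataclass(frozen=True)
class ActivationProtocol:
    """Two-cycle open-close drive.

    Opener envelopes are raised-cosine (sin^2) pulses peaking exactly at
    the open keyframes (75 and 275 ms); closer envelopes rise after each
    open peak, peak at the approach to the closed keyframes (185 and
    365 ms) and decay quickly, on top of a small tonic co-activation that
    holds occlusion at rest.  ``opener_gain`` / ``closer_gain`` scale the
    envelopes (calibrated once so the baseline reaches the 30 mm target
    peak opening); activation levels are clipped to [0, 1].
    """

    duration: float = 0.4                      # s
    open_peaks: tuple[float, ...] = (0.075, 0.275)      # s
    closures: tuple[float, ...] = (0.0, 0.185, 0.365)   # s
    target_peak_opening: float = 30.0          # mm
    opener_rise: float = 0.075                 # s, rise time to each open peak
    opener_fall: float = 0.105                 # s, braking decay after the peak
    closer_fall: float = 0.03                  # s
    closer_rise_delay: float = 0.0             # s after the open peak
    tonic: float = 0.3                         # closer co-activation at rest
    opener_gain: float = 0.9109                # calibrated (see calibrate_opener_gain)
    closer_gain: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.duration:
            raise ValueError("duration must be positive")
        if not (0 <= self.tonic <= 1):
            raise ValueError("tonic must be in [0, 1]")


def _opener_envelope(t: float, p: ActivationProtocol) -> float:
    # asymmetric raised-cosine: rise to the open keyframe, slower braking
    # decay afterwards (eccentric opener activity controls closure speed)
    e = 0.0
    for pk in p.open_peaks:
        if pk - p.opener_rise <= t <= pk:
            e = max(e, np.sin(0.5 * np.pi * (t - pk + p.opener_rise) / p.opener_rise) ** 2)
        elif pk < t <= pk + p.opener_fall:
            e = max(e, np.cos(0.5 * np.pi * (t - pk) / p.opener_fall) ** 2)
    return e


def _closer_envelope(t: float, p: ActivationProtocol) -> float:
    bump = 0.0
    for pk, cl in zip(p.open_peaks, p.closures[1:]):
        rise_start = pk + p.closer_rise_delay
        if rise_start <= t <= cl:
            bump = max(bump, np.sin(0.5 * np.pi * (t - rise_start) / (cl - rise_start)) ** 2)
        elif cl < t <= cl + p.closer_fall:
            bump = max(bump, np.cos(0.5 * np.pi * (t - cl) / p.closer_fall) ** 2)
    return p.tonic + (1.0 - p.tonic) * bump


def activation(t: float, protocol: ActivationProtocol, role: str) -> float:
    """Activation level in [0, 1] for the given role at time t (s)."""
    if not 0.0 <= t <= protocol.duration + 1e-12:
        raise ValueError(f"t = {t} s outside [0, {protocol.duration}] s")
    if role == OPENER:
        env = _opener_envelope(t, protocol)
        return float(np.clip(protocol.opener_gain * env, 0.0, 1.0))
    if role == CLOSER:
        env = _closer_envelope(t, protocol)
        return float(np.clip(protocol.closer_gain * env, 0.0, 1.0))
    raise ValueError(f"role must be opener or closer, got {role!r}")


@dataclass
class RigidBodyState:
    """Mandible state: COM position (mm), orientation, velocities."""

    position: np.ndarray                      # (3,) world, mm
    quaternion: np.ndarray                    # (4,) [x, y, z, w], body->world
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))      # mm/s
    angular_velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))  # rad/s, body frame

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.quaternion = np.asarray(self.quaternion, dtype=float)
        n = np.linalg.norm(self.quaternion)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"quaternion norm must be 1 within 1e-9, got {n}")
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.angular_velocity = np.asarray(self.angular_velocity, dtype=float)

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion)


@dataclass
class DynamicsParams:
    """Passive-element and integrator parameters (mm / N / s units)."""

    gravity: float = 9.81                    # m/s^2 (0 disables)
    passive_elevator_stiffness: float = 0.5  # N/mm per elevator group (linear part)
    passive_wall_amplitude: float = 0.35     # N, progressive-stretch term per elevator
    passive_wall_scale: float = 2.6          # mm, e-folding of the progressive term
    passive_rot_stiffness: tuple[float, float, float] = (2.0e3, 1.0e5, 5.0e4)  # N mm/rad (pitch, roll, yaw)
    passive_rot_damping: tuple[float, float, float] = (160.0, 500.0, 500.0)      # N mm s/rad
    linear_damping: float = 0.05             # N s/mm on COM velocity
    capsule_stiffness: float = 100.0         # N/mm (ligament after slack)
    capsule_slack: float = 1.5               # mm
    capsule_damping: float = 0.2             # N s/mm
    force_combination: str = "vector"        # per-compartment combination rule
    stress_keyframes: tuple[float, ...] = (0.185, 0.275)  # s


@dataclass
class SimulationResult:
    """Time-stamped trajectory, force traces and keyframe stress fields."""

    time_ms: np.ndarray
    positions: np.ndarray                    # (n, 3)
    quaternions: np.ndarray                  # (n, 4)
    opening_mm: np.ndarray
    forces: dict                             # side -> compartment -> component -> (n,)
    mean_force: dict                         # side -> (n,) mean of superior/inferior totals
    dental_force: np.ndarray                 # (n,) total dental contact force magnitude
    stress_fields: dict                      # "<ms>" -> patch name -> per-element Pa
    diagnostics: dict
    energy: np.ndarray | None = None         # (n,) J, when recorded

    def to_dataframe(self):
        import pandas as pd

        cols = {"time_ms": self.time_ms, "opening_mm": self.opening_mm,
                "dental_N": self.dental_force}
        for side in SIDES:
            cols[f"{side}_mean_N"] = self.mean_force[side]
            for comp in ("superior", "inferior"):
                for part in ("total", "elastic", "damping", "friction"):
                    cols[f"{side}_{comp}_{part}_N"] = self.forces[side][comp][part]
        return pd.DataFrame(cols)


def incisal_opening(state: RigidBodyState, geom: MasticatoryGeometry) -> float:
    """Inter-incisal distance (mm): mandibular incisal point vs its maxillary
    counterpart (their closed-pose positions coincide)."""
    R = state.rotation
    pt = state.position + R.apply(geom.landmarks["incisal_point"] - geom.com)
    return float(np.linalg.norm(pt - geom.maxillary_points["incisal"]))


def muscle_forces(
    state: RigidBodyState,
    geom: MasticatoryGeometry,
    muscles: list[MuscleElement],
    t: float,
    protocol: ActivationProtocol,
) -> tuple[np.ndarray, np.ndarray]:
    """Total muscle wrench (force N, torque N mm about the COM).

    Each muscle pulls with ``a_role(t) * peak_force`` along the current
    insertion -> origin unit line; left/right activations are identical
    (bilateral symmetric drive).
    """
    R = state.rotation
    a = {OPENER: activation(t, protocol, OPENER), CLOSER: activation(t, protocol, CLOSER)}
    ins = np.stack([m.insertion for m in muscles]) - geom.com
    org = np.stack([m.origin for m in muscles])
    peaks = np.array([m.peak_force for m in muscles])
    levels = np.array([a[m.role] for m in muscles])
    ins_w = state.position + R.apply(ins)
    d = org - ins_w
    L = np.linalg.norm(d, axis=1)
    if np.any(L < 1e-9):
        bad = [m.name for m, l in zip(muscles, L) if l < 1e-9]
        raise ValueError(f"degenerate muscle line (origin == insertion): {bad}")
    F = (levels * peaks / L)[:, None] * d
    torque = np.cross(ins_w - state.position, F).sum(axis=0)
    return F.sum(axis=0), torque


def _passive_force_mag(stretch: np.ndarray, dp: "DynamicsParams") -> np.ndarray:
    """Passive elevator tension (N) vs stretch beyond rest length (mm):
    gentle linear tone plus a progressive exponential wall near maximal
    opening (what limits mouth opening to the model's ~30 mm)."""
    s = np.maximum(0.0, stretch)
    return dp.passive_elevator_stiffness * s + dp.passive_wall_amplitude * np.expm1(
        s / dp.passive_wall_scale) * (s > 0)


def passive_elevator_wrench(
    state: RigidBodyState,
    geom: MasticatoryGeometry,
    muscles: list[MuscleElement],
    dp: "DynamicsParams",
) -> tuple[np.ndarray, np.ndarray]:
    """Passive elastic recoil of the stretched elevator (closer) muscles.

    Each closer pulls along its line with a tension that is zero at
    occlusion, small through the working range and steeply progressive near
    maximal opening; the recoil closes the jaw and presses the condyles
    up-forward into the fossae at wide opening.  Separate from the
    activation-driven forces.
    """
    closers = [m for m in muscles if m.role == CLOSER]
    if not closers:
        return np.zeros(3), np.zeros(3)
    R = state.rotation
    ins = np.stack([m.insertion for m in closers]) - geom.com
    org = np.stack([m.origin for m in closers])
    L0 = np.linalg.norm(org - (geom.com + ins), axis=1)
    ins_w = state.position + R.apply(ins)
    d = org - ins_w
    L = np.linalg.norm(d, axis=1)
    F = (_passive_force_mag(L - L0, dp) / np.maximum(L, 1e-9))[:, None] * d
    torque = np.cross(ins_w - state.position, F).sum(axis=0)
    return F.sum(axis=0), torque


class _TMJContact:
    """Per-side reduced-order contact evaluator with persistent Prony state."""

    def __init__(self, geom, side, cartilage, disc, params: ContactParams):
        p = geom.params
        self.side = side
        self.cartilage = cartilage
        self.disc = disc
        self.params = params
        self.h = p.stack_thickness
        self.Rf = p.fossa_radius
        self.fossa_center = geom.fossa_center[side]
        self.capsule_anchor = geom.landmarks[side]["condyle_center"].copy()
        fossa = geom.surfaces[side]["fossa"]
        cond = geom.surfaces[side]["condyle"]
        self.fossa_centers = fossa.centers
        self.fossa_normals = fossa.normals      # point toward the condyle
        self.fossa_areas = fossa.areas
        # rest radius per element centroid (centroids sit slightly inside the
        # generating sphere); makes penetration exactly zero in the reference pose
        self.fossa_rest_r = np.linalg.norm(fossa.centers - self.fossa_center, axis=1)
        self.cond_centers_rel = cond.centers - geom.com     # mandible frame
        self.cond_dirs_rel = (cond.centers - geom.landmarks[side]["condyle_center"])
        self.cond_dirs_rel /= np.linalg.norm(self.cond_dirs_rel, axis=1, keepdims=True)
        self.cond_areas = cond.areas
        self.cond_center_rel = geom.landmarks[side]["condyle_center"] - geom.com
        self.disc_cap_cos = np.cos(geom.surfaces[side]["disc_superior"].cap_angle)
        self.fossa_cap_cos = np.cos(fossa.cap_angle)
        self.cap_axis_rel = geom.surfaces[side]["disc_superior"].cap_axis  # mandible frame
        self.fossa_axis = fossa.cap_axis                                   # skull-fixed
        self.hist_sup = PronyBranchState(disc, len(self.fossa_centers))
        self.hist_inf = PronyBranchState(disc, len(self.cond_centers_rel))
        self._primed = False

    def evaluate(self, state: RigidBodyState, dt: float):
        """Returns (force_on_mandible, torque_on_mandible, rec_sup, rec_inf)."""
        R = state.rotation
        p_, v, w_world = state.position, state.velocity, R.apply(state.angular_velocity)
        c = p_ + R.apply(self.cond_center_rel)          # condyle centre, world
        axis_w = R.apply(self.cap_axis_rel)

        # --- superior compartment: foundation = fossa patch (skull-fixed)
        rel = self.fossa_centers - c
        dist = np.linalg.norm(rel, axis=1)
        dirs = rel / dist[:, None]
        pen = np.maximum(0.0, self.fossa_rest_r - dist)
        pen *= (dirs @ axis_w) >= self.disc_cap_cos     # stack coverage
        c_dot = v + np.cross(w_world, c - p_)
        rate = dirs @ c_dot
        v_pt = v + np.cross(w_world, self.fossa_centers - p_)   # condyle material pts
        st_sup = ContactPatchState(pen, rate, v_pt, self.fossa_areas, self.fossa_normals)
        if not self._primed:
            self.hist_sup.prime(pen / self.h)
        rec_sup = evaluate_contact(st_sup, self.cartilage, self.disc, self.params,
                                   history=self.hist_sup, dt=dt,
                                   compartment="superior", side=self.side)

        # --- inferior compartment: foundation = condyle patch (moving)
        cents_w = p_ + R.apply(self.cond_centers_rel)
        d_hat = R.apply(self.cond_dirs_rel)             # outward condyle radials
        g = c - self.fossa_center
        b = d_hat @ g
        disc_term = b * b - (g @ g - self.Rf**2)
        t_ray = -b + np.sqrt(np.maximum(disc_term, 0.0))
        pen_i = np.maximum(0.0, self.Rf - t_ray)
        hit = (c - self.fossa_center) + t_ray[:, None] * d_hat
        pen_i *= (hit @ self.fossa_axis) / self.Rf >= self.fossa_cap_cos  # within the fossa cap
        pen_i = np.where(disc_term > 0.0, pen_i, 0.0)
        v_pt_i = v + np.cross(w_world, cents_w - p_)
        rate_i = np.sum(d_hat * v_pt_i, axis=1)
        if not self._primed:
            self.hist_inf.prime(pen_i / self.h)
            self._primed = True
        st_inf = ContactPatchState(pen_i, rate_i, -v_pt_i, self.cond_areas, d_hat)
        rec_inf = evaluate_contact(st_inf, self.cartilage, self.disc, self.params,
                                   history=self.hist_inf, dt=dt,
                                   compartment="inferior", side=self.side)
        self.last_max_pen = float(max(pen.max(initial=0.0), pen_i.max(initial=0.0)))

        # force on the mandible: average the two discretizations of the stack
        f_sup = rec_sup.total                       # on the condyle (counter-body)
        f_inf = -rec_inf.total                      # reaction on the condyle
        F = 0.5 * (f_sup.sum(axis=0) + f_inf.sum(axis=0))
        tq = 0.5 * (np.cross(self.fossa_centers - p_, f_sup).sum(axis=0)
                    + np.cross(cents_w - p_, f_inf).sum(axis=0))
        return F, tq, rec_sup, rec_inf


def _capsule_force(c, c_dot, fossa_center, dp: DynamicsParams):
    d = c - fossa_center
    dist = float(np.linalg.norm(d))
    if dist <= dp.capsule_slack or dp.capsule_stiffness <= 0:
        return np.zeros(3)
    d_hat = d / dist
    tension = dp.capsule_stiffness * (dist - dp.capsule_slack) + dp.capsule_damping * float(d_hat @ c_dot)
    return -max(tension, 0.0) * d_hat


def simulate_open_close(
    geom: MasticatoryGeometry,
    materials: dict | None = None,
    muscles: list[MuscleElement] | None = None,
    protocol: ActivationProtocol | None = None,
    dt: float = 5e-5,
    contact_params: ContactParams | None = None,
    dynamics_params: DynamicsParams | None = None,
    duration: float | None = None,
    record_energy: bool = False,
    initial_state: RigidBodyState | None = None,
) -> SimulationResult:
    """Integrate the two-cycle open-close protocol; deterministic.

    ``materials`` maps 'cartilage' to a MooneyRivlinMaterial and 'disc' to a
    PronySeries (paper defaults when omitted).  Aborts with
    :class:`SimulationDiverged` on non-finite state or contact bottom-out.
    """
    if materials is None:
        materials = {}
    cartilage = materials.get("cartilage", MooneyRivlinMaterial())
    disc = materials.get("disc", PronySeries())
    muscles = muscles if muscles is not None else default_muscles(geom)
    protocol = protocol or ActivationProtocol()
    cp = contact_params or ContactParams(layer_thickness=geom.params.stack_thickness)
    dp = dynamics_params or DynamicsParams()
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt > min(disc.tau) / 2.0:
        warnings.warn(f"dt = {dt} s under-resolves the fastest Prony branch "
                      f"(tau_min = {min(disc.tau)} s)", stacklevel=2)
    T = duration if duration is not None else protocol.duration
    n_steps = int(round(T / dt)) + 1

    m = geom.params.mandible_mass
    I_b = np.asarray(geom.params.mandible_inertia, dtype=float)
    grav_F = np.array([0.0, 0.0, -m * dp.gravity])

    tmj = {s: _TMJContact(geom, s, cartilage, disc, cp) for s in SIDES}
    incisal_rel = geom.landmarks["incisal_point"] - geom.com
    dental = [(name, geom.dental_points[name] - geom.com, geom.maxillary_points[name])
              for name in geom.dental_points]
    dental_sides = {name: ("right" if name.startswith("right") else
                           "left" if name.startswith("left") else "midline")
                    for name in geom.dental_points}
    down = np.array([0.0, 0.0, -1.0])

    if initial_state is not None:
        state = RigidBodyState(position=initial_state.position.copy(),
                               quaternion=initial_state.quaternion.copy(),
                               velocity=initial_state.velocity.copy(),
                               angular_velocity=initial_state.angular_velocity.copy())
    else:
        state = RigidBodyState(position=geom.com.copy(),
                               quaternion=np.array([0.0, 0.0, 0.0, 1.0]))

    time_ms = np.empty(n_steps)
    positions = np.empty((n_steps, 3))
    quaternions = np.empty((n_steps, 4))
    opening = np.empty(n_steps)
    parts = ("total", "elastic", "damping", "friction")
    forces = {s: {c_: {p__: np.empty(n_steps) for p__ in parts}
                  for c_ in ("superior", "inferior")} for s in SIDES}
    mean_force = {s: np.empty(n_steps) for s in SIDES}
    dental_force = np.empty(n_steps)
    energy = np.empty(n_steps) if record_energy else None
    stress_fields: dict[str, dict[str, np.ndarray]] = {}
    key_steps = {int(round(kt / dt)): kt for kt in dp.stress_keyframes if kt <= T + 1e-12}
    peak_pen = 0.0
    wall0 = _time.perf_counter()

    for k in range(n_steps):
        t = k * dt
        R = state.rotation
        w_world = R.apply(state.angular_velocity)

        F = grav_F.copy()
        rho = R.as_rotvec()
        tq = -np.asarray(dp.passive_rot_stiffness) * rho   # damping applied implicitly

        mF, mT = muscle_forces(state, geom, muscles, min(t, protocol.duration), protocol)
        F = F + mF
        tq = tq + mT
        pF, pT = passive_elevator_wrench(state, geom, muscles, dp)
        F = F + pF
        tq = tq + pT

        recs = {}
        for s in SIDES:
            cF, cT, rec_sup, rec_inf = tmj[s].evaluate(state, dt)
            F = F + cF
            tq = tq + cT
            recs[s] = (rec_sup, rec_inf)
            c_w = state.position + R.apply(tmj[s].cond_center_rel)
            c_dot = state.velocity + np.cross(w_world, c_w - state.position)
            capF = _capsule_force(c_w, c_dot, tmj[s].capsule_anchor, dp)
            F = F + capF
            tq = tq + np.cross(c_w - state.position, capF)

        dtot = 0.0
        for name, rel_m, x_max in dental:
            pt = state.position + R.apply(rel_m)
            pen = float(pt[2] - x_max[2])
            horiz = float(np.hypot(pt[0] - x_max[0], pt[1] - x_max[1]))
            if pen > 0.0 and horiz < 5.0:   # cusp capture range

                v_pt = state.velocity + np.cross(w_world, pt - state.position)
                rec_d = evaluate_dental_contact(pen, float(v_pt[2]), v_pt, down, cp,
                                                side=dental_sides[name],
                                                tangential_offset=pt - x_max)
                fd = rec_d.total.sum(axis=0)
                F = F + fd
                tq = tq + np.cross(pt - state.position, fd)
                dtot += float(np.linalg.norm(fd))

        # record
        time_ms[k] = 1e3 * t
        positions[k] = state.position
        quaternions[k] = state.quaternion
        opening[k] = float(np.linalg.norm(
            state.position + R.apply(incisal_rel) - geom.maxillary_points["incisal"]))
        for s in SIDES:
            rec_sup, rec_inf = recs[s]
            for comp, rec in (("superior", rec_sup), ("inferior", rec_inf)):
                tr = forces[s][comp]
                tr["total"][k] = total_compartment_force(rec, dp.force_combination)
                for part_name, arr in (("elastic", rec.elastic), ("damping", rec.damping),
                                       ("friction", rec.friction)):
                    tr[part_name][k] = (float(np.linalg.norm(arr.sum(axis=0)))
                                        if len(arr) else 0.0)
            mean_force[s][k] = joint_mean_force(forces[s]["superior"]["total"][k],
                                                forces[s]["inferior"]["total"][k])
        dental_force[k] = dtot
        if k in key_steps:
            fields = {}
            for s in SIDES:
                rec_sup, rec_inf = recs[s]
                fields[f"{s}_fossa"] = equivalent_stress_field(rec_sup)
                fields[f"{s}_condyle"] = equivalent_stress_field(rec_inf)
            stress_fields[f"{1e3 * key_steps[k]:.0f}"] = fields
        if record_energy:
            energy[k] = (_mechanical_energy(state, geom, tmj, dp, m, I_b, cartilage, cp)
                         + _passive_elevator_energy(state, geom, muscles, dp))

        peak_pen = max(peak_pen, *(tmj[s].last_max_pen for s in SIDES))

        if k % 200 == 0 and not (np.all(np.isfinite(state.position))
                                 and np.all(np.isfinite(state.velocity))):
            raise SimulationDiverged(f"non-finite state at t = {1e3 * t:.1f} ms")

        # semi-implicit Euler step; passive linear/rotational damping are
        # integrated implicitly (unconditionally stable at any coefficient)
        acc = 1000.0 * F / m
        w_b = state.angular_velocity
        tq_b = R.apply(tq, inverse=True)
        w_dot = 1000.0 * (tq_b - np.cross(w_b, I_b * w_b)) / I_b
        state.velocity = (state.velocity + dt * acc) / (
            1.0 + dt * 1000.0 * dp.linear_damping / m)
        c_rot_b = np.asarray(dp.passive_rot_damping)   # body-frame coefficients
        state.angular_velocity = (w_b + dt * w_dot) / (1.0 + dt * 1000.0 * c_rot_b / I_b)
        w_world_new = R.apply(state.angular_velocity)
        dq = Rotation.from_rotvec(w_world_new * dt)
        q_new = (dq * R).as_quat()
        state.position = state.position + dt * state.velocity
        state.quaternion = q_new / np.linalg.norm(q_new)

    if not np.all(np.isfinite(opening)):
        raise SimulationDiverged("non-finite opening trace")

    diagnostics = {
        "dt_s": dt,
        "n_steps": n_steps,
        "peak_penetration_mm": peak_pen,
        "peak_opening_mm": float(np.max(opening)),
        "wall_time_s": _time.perf_counter() - wall0,
        "opener_gain": protocol.opener_gain,
        "closer_gain": protocol.closer_gain,
    }
    return SimulationResult(
        time_ms=time_ms, positions=positions, quaternions=quaternions,
        opening_mm=opening, forces=forces, mean_force=mean_force,
        dental_force=dental_force, stress_fields=stress_fields,
        diagnostics=diagnostics, energy=energy,
    )


def _passive_elevator_energy(state, geom, muscles, dp) -> float:
    closers = [m for m in muscles if m.role == CLOSER]
    if not closers:
        return 0.0
    R = state.rotation
    ins = np.stack([m.insertion for m in closers]) - geom.com
    org = np.stack([m.origin for m in closers])
    L0 = np.linalg.norm(org - (geom.com + ins), axis=1)
    L = np.linalg.norm(org - (state.position + R.apply(ins)), axis=1)
    s_ = np.maximum(0.0, L - L0)
    k, a, s0 = (dp.passive_elevator_stiffness, dp.passive_wall_amplitude,
                dp.passive_wall_scale)
    e = 0.5 * k * s_**2 + a * s0 * (np.expm1(s_ / s0) - s_ / s0)
    return float(e.sum()) * 1e-3


def _mechanical_energy(state, geom, tmj, dp, m, I_b, cartilage, cp) -> float:
    """Total mechanical energy (J) for the conservative configuration."""
    from .materials import mooney_rivlin_compression_energy_density

    ke = 0.5 * m * float(state.velocity @ state.velocity) * 1e-6
    w_b = state.angular_velocity
    ke += 0.5 * float(w_b @ (I_b * w_b)) * 1e-6
    rho = state.rotation.as_rotvec()
    pe = 0.5 * float(np.asarray(dp.passive_rot_stiffness) @ rho**2) * 1e-3
    pe += m * dp.gravity * float(state.position[2] - geom.com[2]) * 1e-3
    R = state.rotation
    for s in SIDES:
        tc = tmj[s]
        c = state.position + R.apply(tc.cond_center_rel)
        dist = np.linalg.norm(tc.fossa_centers - c, axis=1)
        dirs = (tc.fossa_centers - c) / dist[:, None]
        pen = np.maximum(0.0, tc.fossa_rest_r - dist)
        pen *= (dirs @ R.apply(tc.cap_axis_rel)) >= tc.disc_cap_cos
        lam = 1.0 - pen / tc.h
        w_dens = mooney_rivlin_compression_energy_density(lam, cartilage)   # Pa
        pe += float((w_dens * tc.fossa_areas * tc.h).sum()) * 1e-9
        d = float(np.linalg.norm(c - tc.capsule_anchor))
        if d > dp.capsule_slack:
            pe += 0.5 * dp.capsule_stiffness * (d - dp.capsule_slack) ** 2 * 1e-3
    return ke + pe


def calibrate_opener_gain(
    geom: MasticatoryGeometry,
    materials: dict | None = None,
    protocol: ActivationProtocol | None = None,
    dt: float = 1e-4,
    contact_params: ContactParams | None = None,
    dynamics_params: DynamicsParams | None = None,
    target: float | None = None,
    tol: float = 0.15,
    max_iter: int = 8,
) -> tuple[ActivationProtocol, list[tuple[float, float]]]:
    """Fit the opener gain so the baseline first-cycle peak opening hits the
    target (default: the protocol's 30 mm).  Secant iteration on short runs
    covering the first cycle only; returns the calibrated protocol and the
    (gain, peak) log."""
    protocol = protocol or ActivationProtocol()
    target = target if target is not None else protocol.target_peak_opening
    log: list[tuple[float, float]] = []

    def peak_for(gain: float) -> float:
        res = simulate_open_close(
            geom, materials, None, replace(protocol, opener_gain=gain), dt,
            contact_params, dynamics_params, duration=0.16)
        pk = float(np.max(res.opening_mm))
        log.append((gain, pk))
        return pk

    # peak opening is monotone but saturating in the gain: bracket + bisect
    lo, hi = 0.05, 1.0
    f_lo, f_hi = peak_for(lo) - target, peak_for(hi) - target
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"target {target} mm not bracketed by gains [{lo}, {hi}] "
            f"(peaks {f_lo + target:.1f}, {f_hi + target:.1f} mm)")
    g1, f1 = hi, f_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = peak_for(mid) - target
        g1, f1 = mid, f_mid
        if abs(f_mid) < tol:
            break
        if f_mid > 0:
            hi = mid
        else:
            lo = mid
    return replace(protocol, opener_gain=g1), log
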