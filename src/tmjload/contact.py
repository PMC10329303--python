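"""Reduced-order elastic-foundation contact for the TMJ and dental contacts.

Each contact patch is treated as an independent bed of through-thickness
compressed soft tissue (elastic foundation): per surface element, the
penetration depth divided by the resting layer thickness gives a uniaxial
stretch ``lambda = 1 - delta / h``, the Mooney-Rivlin uniaxial law gives
the elastic normal pressure, the transient Prony branches driven by the
penetration-rate history give the damping pressure, and a regularized
Coulomb law on the tangential slip velocity gives friction.  The total
contact force is the sum of the elastic, damping, and friction components.

Forces in N, pressures in Pa externally / MPa (= N/mm^2) internally,
lengths in mm, velocities in mm/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import (
    MooneyRivlinMaterial,
    PronyBranchState,
    PronySeries,
    mooney_rivlin_uniaxial_stress,
)

__all__ = [
    "ContactPatchState",
    "ContactForceRecord",
    "ContactParams",
    "ContactBottomOut",
    "evaluate_contact",
    "evaluate_dental_contact",
    "total_compartment_force",
    "joint_mean_force",
    "equivalent_stress_field",
]

PA_PER_MPA = 1.0e6


class ContactBottomOut(RuntimeError):
    """An element's penetration reached the layer thickness (bottom-out)."""


@dataclass
class ContactPatchState:
    """Per-element kinematic state of one contact patch at one instant.

    ``penetration`` >= 0 (mm; separation stored as 0), ``penetration_rate``
    (mm/s, positive = approaching), ``slip_velocity`` (n, 3) tangential
    relative velocity of the counter-body (mm/s), ``areas`` (mm^2) and
    outward unit ``normals`` (n, 3) of the foundation elements (normal
    points from the foundation surface toward the counter-body).
    """

    penetration: np.ndarray
    penetration_rate: np.ndarray
    slip_velocity: np.ndarray
    areas: np.ndarray
    normals: np.ndarray

    def __post_init__(self) -> None:
        self.penetration = np.asarray(self.penetration, dtype=float)
        self.penetration_rate = np.asarray(self.penetration_rate, dtype=float)
        self.slip_velocity = np.atleast_2d(np.asarray(self.slip_velocity, dtype=float))
        self.areas = np.asarray(self.areas, dtype=float)
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
        if np.any(self.areas <= 0):
            raise ValueError("element areas must be strictly positive")
        if np.any(self.penetration < 0):
            raise ValueError("penetration must be >= 0 (store separation as 0)")
        norms = np.linalg.norm(self.normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("normals must be unit length")

    def __len__(self) -> int:
        return len(self.penetration)


@dataclass
class ContactForceRecord:
    """Per-element force decomposition for one compartment at one instant."""

    elastic: np.ndarray    # (n, 3) N, on the counter-body
    damping: np.ndarray    # (n, 3) N
    friction: np.ndarray   # (n, 3) N
    normal_pressure: np.ndarray    # (n,) Pa
    tangential_traction: np.ndarray  # (n,) Pa
    compartment: str = "superior"    # {superior, inferior, dental}
    side: str = "right"              # {left, right, midline}

    @property
    def total(self) -> np.ndarray:
        """(n, 3) total per-element force on the counter-body."""
        return self.elastic + self.damping + self.friction

    def counterpart(self) -> "ContactForceRecord":
        """Equal-and-opposite record (force on the foundation body)."""
        return ContactForceRecord(
            elastic=-self.elastic, damping=-self.damping, friction=-self.friction,
            normal_pressure=self.normal_pressure.copy(),
            tangential_traction=self.tangential_traction.copy(),
            compartment=self.compartment, side=self.side,
        )

    @classmethod
    def empty(cls, compartment: str = "superior", side: str = "right") -> "ContactForceRecord":
        z = np.zeros((0, 3))
        return cls(elastic=z, damping=z.copy(), friction=z.copy(),
                   normal_pressure=np.zeros(0), tangential_traction=np.zeros(0),
                   compartment=compartment, side=side)


@dataclass
class ContactParams:
    """Tunable contact-law parameters.

    ``layer_thickness`` (mm) is the resting thickness of the compressed
    compartment layer; ``friction_coefficient`` defaults to 0.01 (synovial
    joints are nearly frictionless); ``damping_source`` selects the Prony
    branches ('prony', TMJ compartments), a constant coefficient
    ('constant', dental contacts) or 'none'; ``slip_regularization`` (mm/s)
    is the speed below which friction ramps linearly to zero.
    """

    layer_thickness: float = 6.0
    friction_coefficient: float = 0.01
    damping_source: str = "prony"          # {prony, constant, none}
    constant_damping: float = 0.3          # N s / mm, dental fallback
    slip_regularization: float = 0.1       # mm/s
    dental_stiffness: float = 4000.0       # N / mm per dental contact point (near-rigid occlusion)
    dental_tangential_stiffness: float = 1000.0  # N / mm occlusal interlock while engaged
    cusp_slope: float = 3.0               # max tangential/normal force ratio (deep interdigitation)

    def __post_init__(self) -> None:
        if not self.layer_thickness > 0:
            raise ValueError(f"layer_thickness must be > 0, got {self.layer_thickness}")
        if self.friction_coefficient < 0:
            raise ValueError(f"friction_coefficient must be >= 0, got {self.friction_coefficient}")
        if self.damping_source not in ("prony", "constant", "none"):
            raise ValueError(f"damping_source must be prony|constant|none, got {self.damping_source}")


def evaluate_contact(
    state: ContactPatchState,
    mat: MooneyRivlinMaterial,
    prony: PronySeries,
    params: ContactParams,
    history: PronyBranchState | None = None,
    dt: float | None = None,
    compartment: str = "superior",
    side: str = "right",
) -> ContactForceRecord:
    """Evaluate one compartment's per-element contact forces.

    Elastic pressure: Mooney-Rivlin uniaxial stress of the layer compressed
    through its thickness (stretch ``1 - delta/h``).  Damping pressure: the
    transient Prony branches driven by the penetration-strain history when
    ``history``/``dt`` are supplied (otherwise the instantaneous-rate
    approximation ``sum(Gi) * eps_dot * tau_eff`` is skipped and the
    'constant' source uses ``c * rate / area``).  Friction opposes slip,
    capped by the Coulomb cone and regularized below the slip threshold.

    Elements with zero penetration contribute exactly zero force.  Raises
    :class:`ContactBottomOut` when any penetration reaches the layer
    thickness.
    """
    n = len(state)
    h = params.layer_thickness
    delta = state.penetration
    if np.any(delta >= h):
        worst = float(delta.max())
        raise ContactBottomOut(
            f"element penetration {worst:.3f} mm reached layer thickness {h} mm "
            f"({compartment}/{side}); reduce the timestep or stiffen the layer"
        )
    active = delta > 0.0

    strain = delta / h
    lam = 1.0 - strain
    # compressive MR stress is negative along the uniaxial path; pressure as magnitude
    p_el = np.zeros(n)
    if np.any(active):
        p_el[active] = -mooney_rivlin_uniaxial_stress(lam[active], mat) / PA_PER_MPA  # MPa
    p_el = np.maximum(p_el, 0.0)

    # damping pressure (MPa)
    p_dm = np.zeros(n)
    if params.damping_source == "prony":
        if history is not None and dt is not None:
            p_dm = history.update(strain, dt)
        else:
            # one-shot evaluation: fastest-branch short-time limit G_i * eps_dot * tau_i
            rate = state.penetration_rate / h
            p_dm = (prony.instantaneous_modulus - prony.G0) * rate * min(prony.tau)
    elif params.damping_source == "constant":
        p_dm = params.constant_damping * state.penetration_rate / state.areas
    p_dm = np.where(active, p_dm, 0.0)
    # contact cannot pull: total normal pressure is non-negative
    p_total = np.maximum(p_el + p_dm, 0.0)
    p_dm = p_total - p_el

    f_el = (p_el * state.areas)[:, None] * state.normals
    f_dm = (p_dm * state.areas)[:, None] * state.normals

    # regularized Coulomb friction on tangential slip
    mu = params.friction_coefficient
    f_fr = np.zeros((n, 3))
    tau_t = np.zeros(n)
    if mu > 0.0 and np.any(active):
        slip = state.slip_velocity
        slip_t = slip - (np.sum(slip * state.normals, axis=1, keepdims=True)) * state.normals
        speed = np.linalg.norm(slip_t, axis=1)
        scale = np.minimum(1.0, speed / params.slip_regularization)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_hat = np.where(speed[:, None] > 0, slip_t / np.maximum(speed, 1e-300)[:, None], 0.0)
        f_mag = mu * p_total * state.areas * scale
        f_mag = np.where(active, f_mag, 0.0)
        f_fr = -f_mag[:, None] * t_hat
        tau_t = np.where(state.areas > 0, f_mag / state.areas, 0.0)

    return ContactForceRecord(
        elastic=f_el, damping=f_dm, friction=f_fr,
        normal_pressure=p_total * PA_PER_MPA,
        tangential_traction=tau_t * PA_PER_MPA,
        compartment=compartment, side=side,
    )


def evaluate_dental_contact(
    penetration: float,
    penetration_rate: float,
    slip_velocity: np.ndarray,
    normal: np.ndarray,
    params: ContactParams,
    side: str = "midline",
    tangential_offset: np.ndarray | None = None,
) -> ContactForceRecord:
    """Single-point dental contact: linear stiffness, constant damping, friction.

    Teeth are treated as rigid (ankylotic) bodies meeting at a stiff elastic
    point contact; there is no disc, so damping is the constant-coefficient
    source.  While engaged, cusp interdigitation also resists tangential
    displacement of the contact point from its occlusal position
    (``tangential_offset``) with stiffness ``dental_tangential_stiffness``
    -- maximal occlusion locks the jaw horizontally, not just vertically.
    Returns a one-element 'dental' record (nominal area 10 mm^2 for
    pressure bookkeeping).
    """
    area = 10.0
    normal = np.asarray(normal, dtype=float)
    if penetration <= 0.0:
        return ContactForceRecord.empty(compartment="dental", side=side)
    f_n_el = params.dental_stiffness * penetration
    f_n = max(f_n_el + params.constant_damping * penetration_rate, 0.0)
    f_n_dm = f_n - f_n_el  # damping clamped so the contact never pulls
    slip = np.asarray(slip_velocity, dtype=float)
    slip_t = slip - np.dot(slip, normal) * normal
    speed = float(np.linalg.norm(slip_t))
    mu = params.friction_coefficient
    if mu > 0.0 and speed > 0.0:
        scale = min(1.0, speed / params.slip_regularization)
        f_fr = -mu * f_n * scale * slip_t / speed
    else:
        f_fr = np.zeros(3)
    f_el = f_n_el * normal
    f_dm = f_n_dm * normal
    if tangential_offset is not None and params.dental_tangential_stiffness > 0:
        off = np.asarray(tangential_offset, dtype=float)
        off = off - np.dot(off, normal) * normal
        f_t = params.dental_tangential_stiffness * off
        # cusp inclines redirect the normal load; they cannot push harder
        # than the occlusal slope allows
        f_t_max = params.cusp_slope * f_n
        f_t_mag = float(np.linalg.norm(f_t))
        if f_t_mag > f_t_max and f_t_mag > 0:
            f_t *= f_t_max / f_t_mag
        f_el = f_el - f_t
        f_dm = f_dm - 0.0002 * params.dental_tangential_stiffness * slip_t  # interlock damping
    return ContactForceRecord(
        elastic=f_el[None, :],
        damping=f_dm[None, :],
        friction=f_fr[None, :],
        normal_pressure=np.array([f_n / area * PA_PER_MPA]),
        tangential_traction=np.array(
            [np.linalg.norm(f_el - np.dot(f_el, normal) * normal + f_fr) / area * PA_PER_MPA]),
        compartment="dental", side=side,
    )


def total_compartment_force(rec: ContactForceRecord, mode: str = "vector") -> float:
    """Combine per-element forces into one number (N) for the compartment.

    ``mode='vector'`` (default): magnitude of the vector sum of all
    elastic + damping + friction element forces.  ``mode='magnitude'``: sum
    of per-element force magnitudes (config-switch alternative).
    """
    if len(rec.elastic) == 0:
        return 0.0
    total = rec.total
    if mode == "vector":
        return float(np.linalg.norm(total.sum(axis=0)))
    if mode == "magnitude":
        return float(np.linalg.norm(total, axis=1).sum())
    raise ValueError(f"mode must be 'vector' or 'magnitude', got {mode!r}")


def joint_mean_force(superior: float, inferior: float) -> float:
    """Mean TMJ contact force: arithmetic mean of the two compartment totals."""
    if superior < 0 or inferior < 0:
        raise ValueError(f"compartment forces must be >= 0, got ({superior}, {inferior})")
    return 0.5 * (superior + inferior)


def equivalent_stress_field(rec: ContactForceRecord) -> np.ndarray:
    """Per-element von Mises equivalent stress (Pa) from (p, tau).

    The local state is uniaxial compression p along the element normal plus
    tangential traction tau: sigma_vm = sqrt(p^2 + 3 tau^2).  Uniaxial p
    alone gives p; pure shear tau alone gives sqrt(3) tau; any hydrostatic
    augmentation leaves the value unchanged (deviatoric invariance).
    """
    p = rec.normal_pressure
    tau = rec.tangential_traction
    return np.sqrt(p**2 + 3.0 * tau**2)
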