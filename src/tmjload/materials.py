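"""Constitutive models for the TMJ soft tissues.

Two laws are used throughout the package:

* Incompressible two-parameter Mooney-Rivlin hyperelasticity,
  ``W = C1 (I1 - 3) + C2 (I2 - 3)``, for the articular cartilage covering
  fossa and condyle.  The default constants are C1 = 4.5e5 Pa and
  C2 = 4.5e2 Pa.

* A quasi-linear viscoelastic (QLV) model for the articular disc: a Prony
  relaxation modulus ``G(t) = G0 + sum_i Gi exp(-t / tau_i)`` applied as a
  hereditary integral over the strain history.  Default branch moduli
  G0..G4 = 0.40, 0.50, 0.50, 0.72, 2.50 MPa with relaxation times
  tau1..tau4 = 50, 5, 0.2, 0.005 s.

Units: Mooney-Rivlin constants and stresses in Pa; Prony moduli and QLV
stresses in MPa (= N/mm^2, convenient for the mm-based contact code);
times in seconds; strains dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MooneyRivlinMaterial",
    "PronySeries",
    "StrainTrace",
    "mooney_rivlin_energy",
    "mooney_rivlin_uniaxial_stress",
    "relaxation_modulus",
    "viscoelastic_stress_history",
    "read_material_config",
    "write_material_config",
]


@dataclass(frozen=True)
class MooneyRivlinMaterial:
    """Incompressible Mooney-Rivlin solid. C1, C2 in Pa."""

    C1: float = 4.5e5
    C2: float = 4.5e2

    def __post_init__(self) -> None:
        if not self.C1 > 0:
            raise ValueError(f"C1 must be > 0, got {self.C1}")
        if self.C2 < 0:
            raise ValueError(f"C2 must be >= 0, got {self.C2}")

    @property
    def shear_modulus(self) -> float:
        """Small-strain shear modulus mu = 2 (C1 + C2), Pa."""
        return 2.0 * (self.C1 + self.C2)


@dataclass(frozen=True)
class PronySeries:
    """Prony relaxation modulus. Moduli in MPa, relaxation times in s.

    ``G0`` is the long-term (equilibrium) modulus; branches are ordered by
    strictly decreasing relaxation time tau1 > tau2 > tau3 > tau4.
    """

    G0: float = 0.40
    G: tuple[float, ...] = (0.50, 0.50, 0.72, 2.50)
    tau: tuple[float, ...] = (50.0, 5.0, 0.2, 0.005)

    def __post_init__(self) -> None:
        if self.G0 < 0:
            raise ValueError(f"G0 must be >= 0, got {self.G0}")
        if len(self.G) != len(self.tau):
            raise ValueError("G and tau must have the same number of branches")
        if any(g < 0 for g in self.G):
            raise ValueError(f"branch moduli must be >= 0, got {self.G}")
        if any(t <= 0 for t in self.tau):
            raise ValueError(f"relaxation times must be > 0, got {self.tau}")
        if any(self.tau[i] <= self.tau[i + 1] for i in range(len(self.tau) - 1)):
            raise ValueError(f"relaxation times must be strictly decreasing, got {self.tau}")

    @property
    def instantaneous_modulus(self) -> float:
        """G(0) = G0 + sum(Gi), MPa."""
        return self.G0 + float(sum(self.G))


@dataclass(frozen=True)
class StrainTrace:
    """Scalar strain samples on a uniform time grid with step ``dt`` (s)."""

    dt: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("strain trace must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise ValueError("strain trace contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(len(self.values))


def mooney_rivlin_energy(I1, I2, mat: MooneyRivlinMaterial) -> np.ndarray | float:
    """Strain-energy density ``W = C1 (I1 - 3) + C2 (I2 - 3)`` in Pa.

    Total on the reals; for inadmissible invariants (I1 or I2 below 3) the
    two-term linear form is simply evaluated and may be negative.
    """
    return mat.C1 * (np.asarray(I1, dtype=float) - 3.0) + mat.C2 * (np.asarray(I2, dtype=float) - 3.0)


def mooney_rivlin_uniaxial_stress(stretch, mat: MooneyRivlinMaterial) -> np.ndarray | float:
    """Cauchy stress (Pa) on the incompressible uniaxial path at stretch lambda.

    sigma = 2 (lambda^2 - 1/lambda) (C1 + C2 / lambda); zero at lambda = 1,
    compressive (negative) for lambda < 1.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError(f"stretch must be > 0, got {stretch}")
    sigma = 2.0 * (lam**2 - 1.0 / lam) * (mat.C1 + mat.C2 / lam)
    return sigma if sigma.ndim else float(sigma)


def mooney_rivlin_compression_energy_density(stretch, mat: MooneyRivlinMaterial):
    """Stored energy per unit reference volume (Pa) along the uniaxial path.

    Antiderivative of -sigma(lambda) from lambda to 1, i.e. the work needed
    to compress the layer to the given stretch; used by the contact energy
    diagnostics.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError(f"stretch must be > 0, got {stretch}")

    def antider(x):
        # int sigma dlam = 2 [C1 x^3/3 + C2 x^2/2 - C1 ln x + C2 / x]
        return 2.0 * (mat.C1 * x**3 / 3.0 + mat.C2 * x**2 / 2.0 - mat.C1 * np.log(x) + mat.C2 / x)

    w = antider(lam) - antider(np.ones_like(lam))
    return w if w.ndim else float(w)


def relaxation_modulus(t, p: PronySeries) -> np.ndarray | float:
    """G(t) = G0 + sum_i Gi exp(-t / tau_i), MPa; t >= 0 (s)."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError(f"time must be >= 0, got {t}")
    g = np.full_like(tt, p.G0, dtype=float)
    for gi, taui in zip(p.G, p.tau):
        g = g + gi * np.exp(-tt / taui)
    return g if g.ndim else float(g)


class PronyBranchState:
    """Recursive internal variables for the transient Prony branches.

    Holds one stress-like internal variable per branch per channel; the
    ``update`` step uses the exponential-integrator formula that is exact
    for strain varying linearly over the step.  Used per contact element by
    the dynamics loop.
    """

    def __init__(self, p: PronySeries, n_channels: int):
        self.p = p
        self.q = np.zeros((len(p.G), n_channels))
        self._last = np.zeros(n_channels)
        self._primed = False

    def prime(self, strain: np.ndarray) -> None:
        """Set the reference strain without generating transient stress."""
        self._last = np.asarray(strain, dtype=float).copy()
        self._primed = True

    def update(self, strain: np.ndarray, dt: float) -> np.ndarray:
        """Advance one step; returns the transient stress sum (MPa)."""
        strain = np.asarray(strain, dtype=float)
        if not self._primed:
            self.prime(np.zeros_like(strain))
        d_eps = strain - self._last
        for b, (gi, taui) in enumerate(zip(self.p.G, self.p.tau)):
            e = np.exp(-dt / taui)
            # exact for piecewise-linear strain over the step
            w = gi * taui / dt * (1.0 - e)
            self.q[b] = e * self.q[b] + w * d_eps
        self._last = strain.copy()
        return self.q.sum(axis=0)


def viscoelastic_stress_history(strain: StrainTrace, p: PronySeries) -> np.ndarray:
    """QLV stress trace (MPa) for a scalar strain history.

    The hereditary integral ``sigma(t) = int G(t - s) d eps(s)`` is
    evaluated with the per-branch recursive exponential update.  The strain
    is interpreted as piecewise linear between samples, with an explicit
    jump at t = 0 when ``strain.values[0] != 0`` (the jump contributes
    ``strain[0] * G(t)`` exactly, so an ideal step response reproduces the
    relaxation modulus to machine precision).

    Warns when dt exceeds tau_min / 2 (shortest branch under-resolved).
    """
    dt = strain.dt
    eps = strain.values
    if dt > min(p.tau) / 2.0:
        warnings.warn(
            f"dt = {dt} s exceeds half the shortest relaxation time "
            f"({min(p.tau)} s); the fastest Prony branch is under-resolved",
            stacklevel=2,
        )
    n = len(eps)
    t = dt * np.arange(n)
    sigma = p.G0 * eps.astype(float).copy()
    # jump at t=0
    for gi, taui in zip(p.G, p.tau):
        sigma += gi * np.exp(-t / taui) * eps[0]
    # piecewise-linear increments after t=0
    d_eps = np.diff(eps)
    for gi, taui in zip(p.G, p.tau):
        e = np.exp(-dt / taui)
        w = gi * taui / dt * (1.0 - e)
        q = 0.0
        out = np.zeros(n)
        for k in range(1, n):
            q = e * q + w * d_eps[k - 1]
            out[k] = q
        sigma += out
    return sigma


# -- flat key-value material config round-trip --------------------------------

def write_material_config(path, cartilage: MooneyRivlinMaterial, disc: PronySeries) -> None:
    """Write a flat ``key = value  # unit`` material parameter file."""
    lines = [
        "# material parameters (flat key-value; units per key)",
        f"cartilage.C1 = {cartilage.C1!r}  # Pa",
        f"cartilage.C2 = {cartilage.C2!r}  # Pa",
        f"disc.G0 = {disc.G0!r}  # MPa",
    ]
    for i, (g, tau) in enumerate(zip(disc.G, disc.tau), start=1):
        lines.append(f"disc.G{i} = {g!r}  # MPa")
        lines.append(f"disc.tau{i} = {tau!r}  # s")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_material_config(path) -> tuple[MooneyRivlinMaterial, PronySeries]:
    kv: dict[str, float] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = float(val)
    cart = MooneyRivlinMaterial(C1=kv["cartilage.C1"], C2=kv["cartilage.C2"])
    n = sum(1 for k in kv if k.startswith("disc.G") and k != "disc.G0")
    disc = PronySeries(
        G0=kv["disc.G0"],
        G=tuple(kv[f"disc.G{i}"] for i in range(1, n + 1)),
        tau=tuple(kv[f"disc.tau{i}"] for i in range(1, n + 1)),
    )
    return cart, disc
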