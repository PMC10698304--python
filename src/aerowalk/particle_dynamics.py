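"""Discrete-phase force balance, drag law, and particle injection.

The Lagrangian force balance per particle is

    dup/dt = f/tau_p (uf - up) + g (rho_p - rho_f)/rho_p

with relaxation time tau_p = rho_p dp^2 / (18 mu) and the drag factor
f = CD Re_p / 24 from the Morsi & Alexander piecewise smooth-sphere
coefficients.  Because the fluid velocity seen by a particle is held
constant over a tracking substep (one eddy interaction), the balance is
linear in up within a substep and is integrated with the exact
exponential update; adaptivity handles the Re_p-dependence of f.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .flow_fields import AIR, FluidProperties

__all__ = [
    "Particle",
    "SizeDistribution",
    "drag_factor",
    "advance",
    "inject",
    "IntegrationError",
    "MORSI_ALEXANDER_COEFFS",
    "VERTICAL_PIPE_DIAMETERS_UM",
    "D2I_DIAMETERS_UM",
]

# Morsi & Alexander (1972) smooth-sphere coefficients, CD = a1 + a2/Re + a3/Re^2,
# one row per particle-Reynolds-number band.  The tracking drag law is stated
# valid for 0 <= Re_p <= 100; higher bands are kept for diagnostics.
MORSI_ALEXANDER_COEFFS = (
    # (Re_low, Re_high, a1, a2, a3)
    (0.0, 0.1, 0.0, 24.0, 0.0),
    (0.1, 1.0, 3.690, 22.73, 0.0903),
    (1.0, 10.0, 1.222, 29.1667, -3.8889),
    (10.0, 100.0, 0.6167, 46.50, -116.67),
    (100.0, 1000.0, 0.3644, 98.33, -2778.0),
)

DRAG_VALID_MAX_REP = 100.0

#: Vertical-pipe benchmark size bins (um).
VERTICAL_PIPE_DIAMETERS_UM = (1.4, 2.5, 3.6, 5.3, 7.2, 10.1, 14.0)
#: Polydisperse inhaler-aerosol size bins (um).
D2I_DIAMETERS_UM = (
    0.206, 0.533, 0.874, 1.498, 2.578, 4.218, 7.297, 11.632, 13.850
)


class IntegrationError(RuntimeError):
    """Raised when the adaptive particle integrator fails to converge."""


def _piecewise_drag(rep_arr: np.ndarray) -> np.ndarray:
    """Piecewise drag factor over an array, no validation (internal)."""
    f = np.ones_like(rep_arr)
    for lo, hi, a1, a2, a3 in MORSI_ALEXANDER_COEFFS:
        m = (rep_arr > lo) & (rep_arr <= hi)
        if np.any(m):
            r = rep_arr[m]
            f[m] = (a1 * r + a2 + a3 / r) / 24.0
    over = rep_arr > MORSI_ALEXANDER_COEFFS[-1][1]
    if np.any(over):
        _, _, a1, a2, a3 = MORSI_ALEXANDER_COEFFS[-1]
        r = rep_arr[over]
        f[over] = (a1 * r + a2 + a3 / r) / 24.0
    return f


def drag_factor(rep):
    """Drag factor f = CD Re_p / 24 (ratio of drag to Stokes drag).

    Accepts scalars or arrays.  f -> 1 as Re_p -> 0 (Stokes limit).  Values
    above Re_p = 100 are outside the validated range and trigger a warning.
    """
    rep_arr = np.asarray(rep, dtype=float)
    if np.any(rep_arr < 0):
        raise ValueError("particle Reynolds number must be non-negative")
    if np.any(rep_arr > DRAG_VALID_MAX_REP):
        warnings.warn(
            f"Re_p above {DRAG_VALID_MAX_REP:g}: drag law outside its "
            "validated range",
            stacklevel=2,
        )
    f = _piecewise_drag(rep_arr)
    return f if rep_arr.ndim else float(f)


class Particle:
    """Discrete-phase state.

    Diameter and density are immutable after construction; the relaxation
    time tau_p = rho_p dp^2/(18 mu) is computed once and kept consistent.
    A particle's fate (``trapped``/``escaped``) is final.
    """

    __slots__ = (
        "_diameter", "_density", "position", "velocity", "_relaxation_time",
        "_state", "_trapped_region", "mass_weight", "bin_index", "eddy",
    )

    def __init__(
        self,
        diameter: float,
        density: float,
        position,
        velocity,
        fluid: FluidProperties = AIR,
        mass_weight: float = 1.0,
        bin_index: int = 0,
    ) -> None:
        if diameter <= 0:
            raise ValueError("diameter must be positive")
        if density <= 0:
            raise ValueError("density must be positive")
        object.__setattr__(self, "_diameter", float(diameter))
        object.__setattr__(self, "_density", float(density))
        object.__setattr__(
            self, "_relaxation_time",
            float(density) * float(diameter) ** 2 / (18.0 * fluid.viscosity),
        )
        self.position = np.asarray(position, dtype=float).copy()
        self.velocity = np.asarray(velocity, dtype=float).copy()
        object.__setattr__(self, "_state", "suspended")
        object.__setattr__(self, "_trapped_region", None)
        self.mass_weight = float(mass_weight)
        self.bin_index = int(bin_index)
        self.eddy = None

    def __setattr__(self, name, value):
        if name in ("_diameter", "_density", "_relaxation_time"):
            raise AttributeError(f"{name[1:]} is immutable after construction")
        if name in ("_state", "_trapped_region"):
            raise AttributeError("use trap()/escape() to change particle fate")
        object.__setattr__(self, name, value)

    diameter = property(lambda self: self._diameter)
    density = property(lambda self: self._density)
    relaxation_time = property(lambda self: self._relaxation_time)
    state = property(lambda self: self._state)
    trapped_region = property(lambda self: self._trapped_region)

    @property
    def radius(self) -> float:
        return self._diameter / 2.0

    def trap(self, region: str) -> None:
        if self._state != "suspended":
            raise ValueError(f"particle fate already {self._state!r}")
        object.__setattr__(self, "_state", "trapped")
        object.__setattr__(self, "_trapped_region", region)

    def escape(self) -> None:
        if self._state != "suspended":
            raise ValueError(f"particle fate already {self._state!r}")
        object.__setattr__(self, "_state", "escaped")

    def __repr__(self) -> str:
        return (
            f"Particle(dp={self._diameter:.3g}, rho={self._density:.3g}, "
            f"state={self._state!r})"
        )


@dataclass(frozen=True)
class SizeDistribution:
    """Polydisperse aerosol as explicit mass-weighted size bins."""

    diameters: tuple      # m
    mass_weights: tuple   # sum to 1

    def __post_init__(self) -> None:
        if len(self.diameters) == 0:
            raise ValueError("size distribution has no bins")
        if len(self.diameters) != len(self.mass_weights):
            raise ValueError("diameters and mass_weights differ in length")
        if any(d <= 0 for d in self.diameters):
            raise ValueError("bin diameters must be positive")
        if any(w <= 0 for w in self.mass_weights):
            raise ValueError("mass weights must be positive")
        total = float(sum(self.mass_weights))
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            object.__setattr__(
                self, "mass_weights",
                tuple(w / total for w in self.mass_weights),
            )

    @classmethod
    def from_bins(cls, diameters_um, mass_weights=None) -> "SizeDistribution":
        d = tuple(float(x) * 1e-6 for x in diameters_um)
        if mass_weights is None:
            mass_weights = (1.0 / len(d),) * len(d)
        return cls(d, tuple(float(w) for w in mass_weights))

    @classmethod
    def lognormal(
        cls, mmad_um: float = 1.72, gsd: float = 1.8, n_bins: int = 9
    ) -> "SizeDistribution":
        """Equal-mass bins of a lognormal mass distribution (MMAD, GSD)."""
        if gsd <= 1.0:
            raise ValueError("GSD must exceed 1")
        dist = stats.lognorm(s=math.log(gsd), scale=mmad_um)
        q = (np.arange(n_bins) + 0.5) / n_bins
        diameters = dist.ppf(q)
        return cls.from_bins(diameters, (1.0 / n_bins,) * n_bins)

    def __len__(self) -> int:
        return len(self.diameters)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def _exact_step(x, v, uf, g_eff, taup, dp, fluid, dt):
    """Exact update of the linear-drag balance over dt with f frozen.

    With f evaluated at the step start the balance is linear; the solution
    is an exponential relaxation towards uf + g_eff tau_p/f, which is also
    the correct implicit (equilibrium) update when tau_p << dt.
    """
    slip = float(np.linalg.norm(uf - v))
    rep = fluid.density * slip * dp / fluid.viscosity
    f = float(_piecewise_drag(np.asarray([rep]))[0])
    tau = taup / f
    v_inf = uf + g_eff * tau
    e = math.exp(-dt / tau)
    v_new = v_inf + (v - v_inf) * e
    x_new = x + v_inf * dt + tau * (v - v_inf) * (1.0 - e)
    return x_new, v_new


_MAX_REFINEMENTS = 20
_REL_TOL = 1e-6


def advance(particle: Particle, fluid_velocity, sample, dt: float) -> Particle:
    """Advance a suspended particle by dt under a frozen instantaneous
    fluid velocity (one eddy interaction substep).

    Adaptive step-halving (at most 20 refinements) controls the relative
    local error from the Re_p-dependence of the drag factor to 1e-6; the
    underlying update is the exact exponential solution of the linearised
    balance, so near hydrodynamic equilibrium a single step suffices.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if particle.state != "suspended":
        raise ValueError("cannot advance a particle whose fate is sealed")
    uf = np.asarray(fluid_velocity, dtype=float)
    fluid = FluidProperties(sample.fluid_density, sample.dynamic_viscosity)
    g_eff = _gravity_effective(sample, particle)
    x, v = particle.position, particle.velocity
    scale = max(float(np.linalg.norm(v)), float(np.linalg.norm(uf)), 1e-12)

    n_sub, level = 1, 0
    while True:
        x1, v1 = x, v
        h = dt / n_sub
        for _ in range(n_sub):
            x1, v1 = _exact_step(
                x1, v1, uf, g_eff, particle.relaxation_time,
                particle.diameter, fluid, h,
            )
        x2, v2 = x, v
        h2 = dt / (2 * n_sub)
        for _ in range(2 * n_sub):
            x2, v2 = _exact_step(
                x2, v2, uf, g_eff, particle.relaxation_time,
                particle.diameter, fluid, h2,
            )
        err = float(np.linalg.norm(v2 - v1)) / scale
        if err < _REL_TOL:
            particle.position = x2
            particle.velocity = v2
            return particle
        level += 1
        n_sub *= 2
        if level > _MAX_REFINEMENTS:
            raise IntegrationError(
                f"no convergence after {_MAX_REFINEMENTS} refinements "
                f"(dt={dt:g}, err={err:g}, dp={particle.diameter:g})"
            )


def _gravity_effective(sample, particle, gravity=None):
    g = np.zeros(3) if gravity is None else np.asarray(gravity, dtype=float)
    if getattr(sample, "gravity", None) is not None:
        g = np.asarray(sample.gravity, dtype=float)
    return g * (particle.density - sample.fluid_density) / particle.density


def advance_with_gravity(
    particle: Particle, fluid_velocity, sample, dt: float, gravity
) -> Particle:
    """:func:`advance` with an explicit gravity vector (m/s^2)."""
    sample.gravity = np.asarray(gravity, dtype=float)  # transient attribute
    try:
        return advance(particle, fluid_velocity, sample, dt)
    finally:
        sample.gravity = None


# ---------------------------------------------------------------------------
# Injection
# ---------------------------------------------------------------------------


def inject(
    field,
    psd: SizeDistribution,
    n_per_bin: int,
    density: float,
    seed: int,
) -> list[Particle]:
    """Inject ``len(psd) * n_per_bin`` particles at the duct inlet.

    Positions are uniform over the inlet cross-section (capped at
    R - dp/2 so no particle is born already touching the wall); the
    initial velocity is axial with the local 1/7th-power-law magnitude.
    Each particle carries the mass weight of its bin divided by the bin
    count.  Fully reproducible from ``seed``.
    """
    if n_per_bin <= 0:
        raise ValueError("n_per_bin must be positive")
    if len(psd) == 0:
        raise ValueError("empty size distribution")
    rng = np.random.default_rng(seed)
    origin, axis = field.inlet_frame()
    # orthonormal in-plane basis
    e1 = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    particles: list[Particle] = []
    for b, (dp, w) in enumerate(zip(psd.diameters, psd.mass_weights)):
        r_max = max(field.radius - dp / 2.0, 0.0)
        u = rng.random(n_per_bin)
        theta = rng.random(n_per_bin) * 2.0 * math.pi
        r = r_max * np.sqrt(u)
        pos = (
            origin
            + r[:, None] * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)
        )
        speed = field.axial_speed(field.radius - r)
        for j in range(n_per_bin):
            particles.append(
                Particle(
                    dp,
                    density,
                    pos[j],
                    speed[j] * axis,
                    fluid=field.fluid,
                    mass_weight=w / n_per_bin,
                    bin_index=b,
                )
            )
    return particles
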