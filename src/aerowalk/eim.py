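"""Discrete random walk eddy interaction model with near-wall corrections.

A particle interacts with a sequence of discrete eddies.  Each eddy holds
a Gaussian vector G (three independent standard normals) for its lifetime
t_e = 2 T_l, where the Lagrangian timescale in k-omega variables is

    T_l = c_l / (0.09 omega),   c_l = 0.15 by default.

The isotropic fluctuation velocity is u' = G sqrt(2k/3).  Modifications
implemented here:

* **Eddy-lifetime floor** — T_l is floored so that its wall-unit value
  T_l+ = T_l u*^2 / nu never falls below a configurable bound (default 3),
  preventing vanishing near-wall timesteps.
* **Anisotropic near-wall damping** — below a (per-region) y+ limit the
  wall-normal fluctuation is replaced by the exponentially damped form
  u_n' = G_n (1 - exp(-0.02 y+)) sqrt(2k/3).
* **NW limit** — within a physical distance of the wall the wall-directed
  instantaneous velocity used for particle tracking is zeroed.
* **Drift correction** — an accumulated mean-fluctuation term
  d(u_i'bar) = sigma (d sigma/d x_i) dt / (1 + Stk), reset at each eddy
  birth, counters the spurious migration of low-Stokes particles towards
  high-dissipation regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Eddy",
    "CorrectionConfig",
    "lagrangian_timescale",
    "spawn_eddy",
    "crossing_time",
    "fluctuation_velocity",
    "drift_update",
    "matida_damping",
]

_CMU = 0.09


@dataclass
class Eddy:
    """One discrete random walk interaction."""

    gauss: np.ndarray                 # (3,) standard-normal vector G
    lifetime: float                   # t_e = 2 T_l, s
    length: float                     # L_e = |u'| t_e, m
    timescale: float                  # the (floored) T_l used, s
    elapsed: float = 0.0
    drift_mean: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.gauss = np.asarray(self.gauss, dtype=float)
        self.drift_mean = np.asarray(self.drift_mean, dtype=float)
        if self.lifetime <= 0:
            raise ValueError("eddy lifetime must be positive")

    @property
    def remaining(self) -> float:
        return max(self.lifetime - self.elapsed, 0.0)


@dataclass(frozen=True)
class CorrectionConfig:
    """Near-wall correction and EIM-modification toggles.

    ``yplus_limit`` may be a number, a per-region mapping, or the string
    ``"correlated"`` (resolved against the flow field by the case runner).
    ``tl_plus_floor=None`` disables the eddy-lifetime floor.  ``nw_limit``
    is a physical distance in meters.  ``interpolation`` selects where
    gridded fields are sampled with intra-cell interpolation:
    ``"everywhere"``, ``"nw_only"`` or ``"off"``.
    """

    cl: float = 0.15
    tl_plus_floor: float | None = 3.0
    yplus_limit: float | dict | str = 0.0
    nw_limit: float = 0.0
    drift_correction: bool = False
    interpolation: str = "off"
    dispersion: bool = True
    nw_zero_mean: bool = True

    def __post_init__(self) -> None:
        if self.cl <= 0:
            raise ValueError("cl must be positive")
        if self.tl_plus_floor is not None and self.tl_plus_floor < 0:
            raise ValueError("tl_plus_floor must be non-negative")
        if self.nw_limit < 0:
            raise ValueError("nw_limit must be non-negative")
        if self.interpolation not in ("everywhere", "nw_only", "off"):
            raise ValueError(f"unknown interpolation mode {self.interpolation!r}")
        if isinstance(self.yplus_limit, (int, float)) and self.yplus_limit < 0:
            raise ValueError("yplus_limit must be non-negative")

    def yplus_limit_for(self, region: str | None = None) -> float:
        if isinstance(self.yplus_limit, dict):
            return float(self.yplus_limit.get(region, 0.0))
        if isinstance(self.yplus_limit, str):
            raise ValueError(
                "symbolic yplus_limit must be resolved against a flow field "
                "before tracking (see cases.run_case)"
            )
        return float(self.yplus_limit)

    def with_(self, **kw) -> "CorrectionConfig":
        return replace(self, **kw)


def timescale_array(sdr, u_star, nu, config: CorrectionConfig):
    """Vectorised Lagrangian timescale with the optional T_l+ floor."""
    sdr = np.asarray(sdr, dtype=float)
    if np.any(sdr <= 0):
        raise ValueError("specific dissipation rate must be positive")
    tl = config.cl / (_CMU * sdr)
    if config.tl_plus_floor is not None:
        u_star = np.asarray(u_star, dtype=float)
        floor = np.where(
            u_star > 0,
            config.tl_plus_floor * nu / np.maximum(u_star, 1e-150) ** 2,
            0.0,
        )
        tl = np.maximum(tl, floor)
    return tl


def lagrangian_timescale(sample, config: CorrectionConfig) -> float:
    """T_l = c_l/(0.09 omega), floored so that T_l+ = T_l u*^2/nu >= bound."""
    tl = timescale_array(
        sample.sdr, sample.friction_velocity, sample.kinematic_viscosity, config
    )
    return float(tl)


def spawn_eddy(sample, rng, config: CorrectionConfig) -> Eddy:
    """Draw a fresh eddy at the particle's location.

    G are three independent untruncated standard normals; the lifetime is
    twice the (floored) Lagrangian timescale and the length is |u'| t_e.
    The drift-corrected mean fluctuation is zeroed at birth.
    """
    gauss = rng.standard_normal(3)
    tl = lagrangian_timescale(sample, config)
    lifetime = 2.0 * tl
    u_prime = gauss * sample.sigma
    length = float(np.linalg.norm(u_prime)) * lifetime
    return Eddy(gauss=gauss, lifetime=lifetime, length=length, timescale=tl)


def crossing_time(particle, eddy: Eddy, slip: float) -> float | None:
    """Eddy crossing time -tau_p ln(1 - L_e/(tau_p |uf - up|)).

    Returns ``None`` when the particle never crosses the eddy (zero slip,
    or eddy length at least the stopping distance tau_p * slip).
    """
    if slip < 0:
        raise ValueError("slip speed must be non-negative")
    taup = particle.relaxation_time
    if slip == 0.0 or eddy.length == 0.0:
        # no relative motion, or no turbulence: the eddy is never crossed
        return None
    arg = 1.0 - eddy.length / (taup * slip)
    if arg <= 0.0:
        return None
    return -taup * math.log(arg)


def matida_damping(yplus):
    """Near-wall damping factor 1 - exp(-0.02 y+) for the wall-normal
    fluctuation; monotone non-decreasing, 0 at the wall, -> 1 far away."""
    return 1.0 - np.exp(-0.02 * np.asarray(yplus, dtype=float))


def fluctuation_velocity(
    sample,
    eddy: Eddy,
    particle_yplus: float,
    config: CorrectionConfig,
    region: str | None = None,
) -> np.ndarray:
    """Instantaneous fluctuation velocity seen by the particle.

    Starts from the isotropic u' = G sqrt(2k/3); below the regional y+
    limit the wall-normal component is replaced by its damped form (the
    same G_n, so the isotropic and damped variants are comparable eddy by
    eddy); the drift-corrected mean is added if enabled; within the NW
    limit the wall-normal fluctuation is zeroed (applied last, so the NW
    limit always wins).
    """
    if not config.dispersion:
        return np.zeros(3)
    sigma = sample.sigma
    u = eddy.gauss * sigma
    n = sample.wall_normal
    limit = config.yplus_limit_for(region)
    if limit > 0.0 and particle_yplus < limit:
        gn = float(np.dot(eddy.gauss, n))
        un_damped = gn * float(matida_damping(particle_yplus)) * sigma
        u = u - np.dot(u, n) * n + un_damped * n
    if config.drift_correction:
        u = u + eddy.drift_mean
    if config.nw_limit > 0.0 and sample.wall_distance < config.nw_limit:
        u = u - np.dot(u, n) * n
    return u


def drift_update(eddy: Eddy, sample, stk: float, dt: float) -> Eddy:
    """Accumulate the drift-corrected mean fluctuation over a timestep.

    d(u_i'bar) = sigma (d sigma/dx_i) dt / (1 + Stk), with Stk = tau_p/T_l;
    the gradient component paired with each fluctuation component is the
    matching spatial direction.  Large particles (Stk -> inf) are left
    undisturbed.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    increment = sample.sigma * sample.sigma_gradient * dt / (1.0 + stk)
    eddy.drift_mean = eddy.drift_mean + increment
    return eddy
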