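"""Continuous-phase flow fields for Lagrangian aerosol tracking.

Two families of fields are provided:

* Analytic fully developed turbulent duct fields (straight pipe and a
  90-degree bend with the axial profile swept along the bend centerline).
  The mean axial velocity follows the 1/7th power law matched to the bulk
  flow rate; the turbulent kinetic energy ``k`` and specific dissipation
  rate ``omega`` come from algebraic equilibrium boundary-layer closures
  parameterised by the friction velocity (Blasius friction factor).
* Gridded fields read from columnar CSV or legacy-ASCII VTK structured
  grids, sampled either cell-centered (host node value) or by an
  inverse-distance-weighted average of the host and adjacent nodes.

All quantities are SI.  The duct axis is +z (right-handed Cartesian).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "FluidProperties",
    "FlowSample",
    "FlowField",
    "AnalyticPipeField",
    "CurvedTubeField",
    "GriddedField",
    "make_analytic_pipe_field",
    "load_gridded_field",
    "sample",
    "DomainError",
]

#: Reynolds-number range over which the analytic closures are exercised.
TURBULENT_RE_RANGE = (4_000.0, 50_000.0)

_CMU = 0.09
_KAPPA = 0.41


class DomainError(ValueError):
    """Raised when a field is sampled outside its domain."""


@dataclass(frozen=True)
class FluidProperties:
    """Continuous-phase properties (default: air at ~22 °C)."""

    density: float = 1.204        # kg/m^3
    viscosity: float = 1.81e-5    # Pa s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


AIR = FluidProperties()


@dataclass
class FlowSample:
    """Local continuous-phase state at a point.

    ``sigma_gradient`` is the spatial gradient of the isotropic fluctuation
    scale sigma = sqrt(2k/3), used by the drift correction.
    """

    mean_velocity: np.ndarray      # (3,) m/s
    tke: float                     # m^2/s^2
    sdr: float                     # 1/s
    wall_distance: float           # m
    wall_normal: np.ndarray        # (3,) unit vector pointing away from wall
    friction_velocity: float       # m/s
    fluid_density: float           # kg/m^3
    dynamic_viscosity: float       # Pa s
    sigma_gradient: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )                              # (3,) 1/s

    def __post_init__(self) -> None:
        self.mean_velocity = np.asarray(self.mean_velocity, dtype=float)
        self.wall_normal = np.asarray(self.wall_normal, dtype=float)
        self.sigma_gradient = np.asarray(self.sigma_gradient, dtype=float)
        if self.tke < 0:
            raise ValueError("tke must be non-negative")
        if self.tke > 0 and self.sdr <= 0:
            raise ValueError("sdr must be positive wherever tke > 0")
        if self.wall_distance < 0:
            raise ValueError("wall_distance must be non-negative")
        if self.fluid_density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def yplus(self) -> float:
        """Dimensionless wall distance y+ = y u* rho / mu."""
        return (
            self.wall_distance
            * self.friction_velocity
            * self.fluid_density
            / self.dynamic_viscosity
        )

    @property
    def sigma(self) -> float:
        """Isotropic fluctuation velocity scale sqrt(2k/3), m/s."""
        return math.sqrt(2.0 * self.tke / 3.0)

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.fluid_density


# ---------------------------------------------------------------------------
# Equilibrium boundary-layer closures for analytic fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalyticProfile:
    """Algebraic wall-unit profiles for k and omega.

    ``k+`` rises as y+^2 in the viscous sublayer, peaks at ``k_peak_plus``
    near ``yplus_peak`` (buffer layer), relaxes to the equilibrium
    log-region plateau ``k_log_plus`` (~ 1/sqrt(Cmu)), and decays across
    the outer region to the configurable core level ``k_core_plus``
    (fraction of duct half-width set by the second argument of
    :meth:`k_plus`).  ``omega`` blends the viscous-sublayer asymptote
    6 nu / (0.075 y^2) with the log-region form u*/(sqrt(0.09) kappa y).
    Both shapes are deliberately simple and swappable: the eddy
    interaction model consumes only (k, omega, y+).
    """

    k_peak_plus: float = 4.5
    yplus_peak: float = 15.0
    k_log_plus: float = 1.0 / math.sqrt(_CMU)   # ~3.33
    k_core_plus: float = 0.8

    def k_plus(self, yplus: np.ndarray, xi: np.ndarray = 0.0) -> np.ndarray:
        """k in wall units at wall distance y+ and relative depth
        xi = y / (duct half-width), 0 at the wall, 1 on the axis."""
        yplus = np.asarray(yplus, dtype=float)
        xi = np.clip(np.asarray(xi, dtype=float), 0.0, 1.0)
        # outer decay of the log plateau towards the core level
        k_outer = self.k_core_plus + (self.k_log_plus - self.k_core_plus) * (
            1.0 - xi
        ) ** 2
        wall_damp = 1.0 - np.exp(-((yplus / 12.0) ** 2))
        # buffer-layer excess over the plateau, peaking near yplus_peak
        r = yplus / self.yplus_peak
        amp = self.k_peak_plus - self.k_log_plus * (
            1.0 - math.exp(-((self.yplus_peak / 12.0) ** 2))
        )
        bump = amp * r**2 * np.exp(2.0 * (1.0 - r))
        return k_outer * wall_damp + bump

    def omega(self, y: np.ndarray, u_star: float, nu: float) -> np.ndarray:
        y = np.maximum(np.asarray(y, dtype=float), 1e-9)
        om_log = u_star / (math.sqrt(_CMU) * _KAPPA * y)
        om_vis = 6.0 * nu / (0.075 * y**2)
        return np.sqrt(om_log**2 + om_vis**2)


# ---------------------------------------------------------------------------
# Field base class
# ---------------------------------------------------------------------------


class FlowField:
    """A sampleable continuous-phase flow field.

    Subclasses implement :meth:`sample_batch` over arrays of positions;
    :meth:`sample` is the scalar convenience wrapper returning a
    :class:`FlowSample`.
    """

    fluid: FluidProperties
    sampling_mode: str = "interpolated"

    def sample_batch(self, positions: np.ndarray) -> dict:
        raise NotImplementedError

    def contains(self, positions: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def sample(self, position) -> FlowSample:
        p = np.asarray(position, dtype=float).reshape(1, 3)
        if not bool(self.contains(p)[0]):
            raise DomainError(f"position {position} is outside the flow domain")
        b = self.sample_batch(p)
        return FlowSample(
            mean_velocity=b["mean_velocity"][0],
            tke=float(b["tke"][0]),
            sdr=float(b["sdr"][0]),
            wall_distance=float(b["wall_distance"][0]),
            wall_normal=b["wall_normal"][0],
            friction_velocity=float(b["friction_velocity"][0]),
            fluid_density=self.fluid.density,
            dynamic_viscosity=self.fluid.viscosity,
            sigma_gradient=b["sigma_gradient"][0],
        )


def sample(flow_field: FlowField, position) -> FlowSample:
    """Sample ``flow_field`` at ``position`` (module-level convenience)."""
    return flow_field.sample(position)


# ---------------------------------------------------------------------------
# Analytic duct fields
# ---------------------------------------------------------------------------


class _AnalyticDuctField(FlowField):
    """Shared machinery for analytic ducts (straight pipe, swept bend)."""

    def __init__(
        self,
        diameter: float,
        bulk_velocity: float,
        fluid: FluidProperties,
        reynolds: float,
        profile: AnalyticProfile,
    ) -> None:
        if diameter <= 0:
            raise ValueError("diameter must be positive")
        lo, hi = TURBULENT_RE_RANGE
        if not (lo <= reynolds <= hi):
            raise ValueError(
                f"Re={reynolds:.0f} outside the supported turbulent range "
                f"[{lo:.0f}, {hi:.0f}] for the analytic closures"
            )
        self.diameter = diameter
        self.radius = diameter / 2.0
        self.bulk_velocity = bulk_velocity
        self.fluid = fluid
        self.reynolds = reynolds
        self.profile = profile
        # Blasius smooth-pipe friction factor -> friction velocity.
        self.friction_factor = 0.316 * reynolds ** (-0.25)
        self.friction_velocity = bulk_velocity * math.sqrt(self.friction_factor / 8.0)
        # 1/7th power law: U_bulk / U_centerline = 2 n^2 / ((n+1)(2n+1)), n=7.
        self.centerline_velocity = bulk_velocity * 60.0 / 49.0

    # --- geometry hooks ---------------------------------------------------

    def local_coords(self, positions: np.ndarray):
        """Return (s, wall_distance, wall_normal, tangent) arrays.

        ``s`` is arc length along the duct centerline; ``wall_normal``
        points away from the wall (towards the centerline); ``tangent``
        is the local unit flow direction.
        """
        raise NotImplementedError

    @property
    def path_length(self) -> float:
        raise NotImplementedError

    def contains(self, positions: np.ndarray) -> np.ndarray:
        s, yw, _, _ = self.local_coords(np.asarray(positions, dtype=float))
        return (yw >= 0) & (s >= 0) & (s <= self.path_length)

    # --- profiles ---------------------------------------------------------

    def axial_speed(self, wall_distance: np.ndarray) -> np.ndarray:
        yw = np.clip(np.asarray(wall_distance, dtype=float), 0.0, self.radius)
        return self.centerline_velocity * (yw / self.radius) ** (1.0 / 7.0)

    def tke(self, wall_distance: np.ndarray) -> np.ndarray:
        yw = np.clip(np.asarray(wall_distance, dtype=float), 0.0, self.radius)
        nu = self.fluid.kinematic_viscosity
        yplus = yw * self.friction_velocity / nu
        xi = yw / self.radius
        return self.profile.k_plus(yplus, xi) * self.friction_velocity**2

    def sdr(self, wall_distance: np.ndarray) -> np.ndarray:
        yw = np.clip(np.asarray(wall_distance, dtype=float), 0.0, self.radius)
        return self.profile.omega(
            yw, self.friction_velocity, self.fluid.kinematic_viscosity
        )

    def _sigma(self, wall_distance: np.ndarray) -> np.ndarray:
        return np.sqrt(2.0 * self.tke(wall_distance) / 3.0)

    def _dsigma_dy(self, wall_distance: np.ndarray) -> np.ndarray:
        # Finite-difference step small relative to the wall distance so the
        # probe never crosses the wall.
        yw = np.asarray(wall_distance, dtype=float)
        h = np.minimum(1e-3 * self.diameter, 0.1 * np.maximum(yw, 1e-12))
        h = np.maximum(h, 1e-10)
        lo = np.maximum(yw - h, 0.0)
        hi = np.minimum(yw + h, self.radius)
        span = np.maximum(hi - lo, 1e-300)
        return (self._sigma(hi) - self._sigma(lo)) / span

    def sample_batch(self, positions: np.ndarray) -> dict:
        positions = np.asarray(positions, dtype=float)
        _, yw, normal, tangent = self.local_coords(positions)
        yw = np.clip(yw, 0.0, self.radius)
        speed = self.axial_speed(yw)
        n = positions.shape[0]
        # sigma varies only with wall distance: gradient along wall normal.
        grad = self._dsigma_dy(yw)[:, None] * normal
        return {
            "mean_velocity": speed[:, None] * tangent,
            "tke": self.tke(yw),
            "sdr": self.sdr(yw),
            "wall_distance": yw,
            "wall_normal": normal,
            "friction_velocity": np.full(n, self.friction_velocity),
            "sigma_gradient": grad,
        }

    def wall_distance_batch(self, positions: np.ndarray) -> np.ndarray:
        _, yw, _, _ = self.local_coords(np.asarray(positions, dtype=float))
        return yw

    # --- helpers for injection and shell statistics -----------------------

    def inlet_frame(self):
        """Inlet centerline point and unit flow direction."""
        raise NotImplementedError

    def shell_cell_table(self, n_radial: int = 400) -> pd.DataFrame:
        """Discretise the cross-section into annular cells for volume stats.

        Returns a frame with columns value-agnostic geometry (``wall_distance``,
        ``volume``, ``yplus``) plus local ``speed`` and the wall-distance cell
        Reynolds number ``cell_re`` used by the y+ limit correlation.  Volumes
        are per unit duct length (only ratios matter in volume averages).
        """
        edges = np.linspace(0.0, self.radius, n_radial + 1)
        yw = 0.5 * (edges[:-1] + edges[1:])
        r_out = self.radius - edges[:-1]
        r_in = self.radius - edges[1:]
        vol = math.pi * (r_out**2 - r_in**2)
        speed = self.axial_speed(yw)
        nu = self.fluid.kinematic_viscosity
        yplus = yw * self.friction_velocity / nu
        cell_re = yw * speed / nu
        return pd.DataFrame(
            {
                "wall_distance": yw,
                "volume": vol,
                "yplus": yplus,
                "speed": speed,
                "cell_re": cell_re,
                "tke": self.tke(yw),
            }
        )


class AnalyticPipeField(_AnalyticDuctField):
    """Fully developed turbulent flow in a straight pipe along +z."""

    def __init__(
        self,
        diameter: float,
        bulk_velocity: float,
        length: float,
        fluid: FluidProperties = AIR,
        reynolds: float | None = None,
        profile: AnalyticProfile = AnalyticProfile(),
    ) -> None:
        if length <= 0:
            raise ValueError("length must be positive")
        if reynolds is None:
            reynolds = bulk_velocity * diameter / fluid.kinematic_viscosity
        super().__init__(diameter, bulk_velocity, fluid, reynolds, profile)
        self.length = length

    @property
    def path_length(self) -> float:
        return self.length

    def local_coords(self, positions: np.ndarray):
        positions = np.atleast_2d(positions)
        x, y, z = positions[:, 0], positions[:, 1], positions[:, 2]
        r = np.hypot(x, y)
        yw = self.radius - r
        safe = np.maximum(r, 1e-30)
        normal = np.stack([-x / safe, -y / safe, np.zeros_like(x)], axis=1)
        on_axis = r < 1e-12
        if np.any(on_axis):
            normal[on_axis] = np.array([-1.0, 0.0, 0.0])
        tangent = np.zeros_like(positions)
        tangent[:, 2] = 1.0
        return z, yw, normal, tangent

    def inlet_frame(self):
        return np.zeros(3), np.array([0.0, 0.0, 1.0])


class CurvedTubeField(_AnalyticDuctField):
    """90-degree bend with straight extensions, swept-profile approximation.

    The fully developed axial profile is swept along the centerline with
    solid-body turning: no Dean (secondary-flow) vortices are modeled.  The
    centerline runs along +z through the inlet extension, turns 90 degrees
    in the x-z plane, and exits along +x.
    """

    def __init__(
        self,
        diameter: float,
        bend_ratio: float,
        extension_lengths: float,
        bulk_velocity: float,
        fluid: FluidProperties = AIR,
        reynolds: float | None = None,
        profile: AnalyticProfile = AnalyticProfile(),
    ) -> None:
        if reynolds is None:
            reynolds = bulk_velocity * diameter / fluid.kinematic_viscosity
        super().__init__(diameter, bulk_velocity, fluid, reynolds, profile)
        if bend_ratio * self.radius <= self.radius:
            raise ValueError("bend radius must exceed the tube radius")
        self.bend_ratio = bend_ratio
        self.bend_radius = bend_ratio * self.radius
        self.extension_length = extension_lengths
        self._s_bend_start = extension_lengths
        self._s_bend_end = extension_lengths + self.bend_radius * math.pi / 2.0
        self._center = np.array([self.bend_radius, 0.0, extension_lengths])

    @property
    def path_length(self) -> float:
        return self._s_bend_end + self.extension_length

    def local_coords(self, positions: np.ndarray):
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        x, y, z = positions[:, 0], positions[:, 1], positions[:, 2]
        n = positions.shape[0]
        s = np.empty(n)
        yw = np.empty(n)
        normal = np.empty((n, 3))
        tangent = np.empty((n, 3))

        rb, l1 = self.bend_radius, self._s_bend_start
        # Bend-plane angle about the bend center (x-z plane).
        phi = np.arctan2(z - l1, rb - x)
        in_inlet = phi <= 0.0
        in_outlet = phi >= math.pi / 2.0
        in_bend = ~(in_inlet | in_outlet)

        if np.any(in_inlet):
            i = in_inlet
            s[i] = z[i]
            r = np.hypot(x[i], y[i])
            yw[i] = self.radius - r
            safe = np.maximum(r, 1e-30)
            nrm = np.stack([-x[i] / safe, -y[i] / safe, np.zeros(i.sum())], axis=1)
            nrm[r < 1e-12] = [-1.0, 0.0, 0.0]
            normal[i] = nrm
            tangent[i] = [0.0, 0.0, 1.0]
        if np.any(in_bend):
            i = in_bend
            ph = phi[i]
            s[i] = l1 + rb * ph
            # in-plane distance from the bend center
            d = np.hypot(x[i] - rb, z[i] - l1)
            # offset from the swept centerline circle
            dr = d - rb
            yw[i] = self.radius - np.hypot(dr, y[i])
            # unit vector from bend center towards the point, in-plane
            e_r = np.stack(
                [
                    (x[i] - rb) / np.maximum(d, 1e-30),
                    np.zeros(i.sum()),
                    (z[i] - l1) / np.maximum(d, 1e-30),
                ],
                axis=1,
            )
            off = dr[:, None] * e_r
            off[:, 1] = y[i]
            dist = np.maximum(np.linalg.norm(off, axis=1), 1e-30)
            nrm = -off / dist[:, None]
            deg = np.hypot(dr, y[i]) < 1e-12
            nrm[deg] = -e_r[deg]
            normal[i] = nrm
            tangent[i] = np.stack(
                [np.sin(ph), np.zeros(i.sum()), np.cos(ph)], axis=1
            )
        if np.any(in_outlet):
            i = in_outlet
            s[i] = self._s_bend_end + (x[i] - rb)
            r = np.hypot(y[i], z[i] - (l1 + rb))
            yw[i] = self.radius - r
            safe = np.maximum(r, 1e-30)
            nrm = np.stack(
                [np.zeros(i.sum()), -y[i] / safe, -(z[i] - (l1 + rb)) / safe],
                axis=1,
            )
            nrm[r < 1e-12] = [0.0, -1.0, 0.0]
            normal[i] = nrm
            tangent[i] = [1.0, 0.0, 0.0]
        return s, yw, normal, tangent

    def inlet_frame(self):
        return np.zeros(3), np.array([0.0, 0.0, 1.0])


def make_analytic_pipe_field(
    diameter: float,
    flow_rate: float | None = None,
    reynolds: float | None = None,
    length: float = 1.02,
    fluid: FluidProperties = AIR,
    profile: AnalyticProfile = AnalyticProfile(),
) -> AnalyticPipeField:
    """Build an analytic fully developed turbulent pipe field.

    Exactly one of ``flow_rate`` (m^3/s, sets the bulk velocity) or
    ``reynolds`` is required; when both are given the flow rate sets the
    bulk velocity and ``reynolds`` is the nominal value used in the Blasius
    friction factor (the benchmark pipe case quotes both).
    """
    if flow_rate is None and reynolds is None:
        raise ValueError("provide flow_rate or reynolds")
    area = math.pi * diameter**2 / 4.0
    if flow_rate is not None:
        if flow_rate <= 0:
            raise ValueError("flow_rate must be positive")
        bulk = flow_rate / area
    else:
        bulk = reynolds * fluid.kinematic_viscosity / diameter
    if reynolds is None:
        reynolds = bulk * diameter / fluid.kinematic_viscosity
    return AnalyticPipeField(
        diameter, bulk, length, fluid=fluid, reynolds=reynolds, profile=profile
    )


# ---------------------------------------------------------------------------
# Gridded fields
# ---------------------------------------------------------------------------

_GRID_COLUMNS = ("x", "y", "z", "u", "v", "w", "k", "omega", "wall_distance")


class GriddedField(FlowField):
    """Node-based field sampled cell-centered or inverse-distance weighted.

    In ``cell_centered`` mode a query returns the host (nearest) node's
    values; in ``interpolated`` mode an inverse-distance-weighted average
    over the host and adjacent nodes.  Wall normals are estimated from the
    local gradient of the wall-distance field; the friction velocity, when
    not supplied, uses the equilibrium estimate u* = Cmu^(1/4) sqrt(k).
    """

    def __init__(
        self,
        nodes: np.ndarray,
        values: dict,
        mode: str = "interpolated",
        fluid: FluidProperties = AIR,
        friction_velocity: float | None = None,
        n_neighbors: int = 8,
    ) -> None:
        if mode not in ("cell_centered", "interpolated"):
            raise ValueError(f"unknown sampling mode {mode!r}")
        self.nodes = np.asarray(nodes, dtype=float)
        self.values = {k: np.asarray(v, dtype=float) for k, v in values.items()}
        for key in ("u", "v", "w", "k", "omega", "wall_distance"):
            if key not in self.values:
                raise ValueError(f"gridded field is missing column {key!r}")
        self.sampling_mode = mode
        self.fluid = fluid
        self._u_star = friction_velocity
        self.n_neighbors = min(n_neighbors, len(self.nodes))
        self._tree = cKDTree(self.nodes)
        pad = 1e-9 + 0.05 * float(
            np.max(self.nodes.max(axis=0) - self.nodes.min(axis=0), initial=0.0)
        )
        self._lo = self.nodes.min(axis=0) - pad
        self._hi = self.nodes.max(axis=0) + pad
        # sigma = sqrt(2k/3) per node, for drift-correction gradients
        self._sigma_nodes = np.sqrt(2.0 * self.values["k"] / 3.0)

    def contains(self, positions: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(positions)
        return np.all((p >= self._lo) & (p <= self._hi), axis=1)

    def _neighbors(self, positions: np.ndarray):
        d, idx = self._tree.query(np.atleast_2d(positions), k=self.n_neighbors)
        if self.n_neighbors == 1:
            d, idx = d[:, None], idx[:, None]
        return d, idx

    def sample_batch(self, positions: np.ndarray) -> dict:
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        d, idx = self._neighbors(positions)
        if self.sampling_mode == "cell_centered":
            w = np.zeros_like(d)
            w[:, 0] = 1.0
        else:
            w = 1.0 / np.maximum(d, 1e-150) ** 2
            # exact hit: the zero-distance node dominates
            hit = d[:, 0] < 1e-12
            if np.any(hit):
                w[hit] = 0.0
                w[hit, 0] = 1.0
        w = w / w.sum(axis=1, keepdims=True)

        def interp(name):
            return np.sum(self.values[name][idx] * w, axis=1)

        u = np.stack([interp("u"), interp("v"), interp("w")], axis=1)
        k = interp("k")
        omega = np.maximum(interp("omega"), 1e-12)
        yw = interp("wall_distance")

        grad_y = self._ls_gradient(positions, idx, self.values["wall_distance"])
        norms = np.linalg.norm(grad_y, axis=1)
        normal = np.where(
            norms[:, None] > 1e-12, grad_y / np.maximum(norms, 1e-30)[:, None],
            np.array([0.0, 0.0, 1.0]),
        )
        grad_sigma = self._ls_gradient(positions, idx, self._sigma_nodes)
        if self._u_star is not None:
            u_star = np.full(len(positions), self._u_star)
        else:
            u_star = _CMU**0.25 * np.sqrt(np.maximum(k, 0.0))
        return {
            "mean_velocity": u,
            "tke": np.maximum(k, 0.0),
            "sdr": omega,
            "wall_distance": np.maximum(yw, 0.0),
            "wall_normal": normal,
            "friction_velocity": u_star,
            "sigma_gradient": grad_sigma,
        }

    def wall_distance_batch(self, positions: np.ndarray) -> np.ndarray:
        return self.sample_batch(positions)["wall_distance"]

    def _ls_gradient(self, positions, idx, node_values):
        """Least-squares linear gradient of a nodal field at each query."""
        n, kn = idx.shape
        out = np.zeros((n, 3))
        if kn < 4:
            return out  # not enough neighbors to resolve a 3D gradient
        dX = self.nodes[idx] - positions[:, None, :]      # (n, kn, 3)
        dv = node_values[idx]                             # (n, kn)
        dv = dv - dv.mean(axis=1, keepdims=True)
        dXc = dX - dX.mean(axis=1, keepdims=True)
        # normal equations per query; rank-deficient fits fall back to zero
        A = np.einsum("nki,nkj->nij", dXc, dXc)
        b = np.einsum("nki,nk->ni", dXc, dv)
        for i in range(n):
            try:
                out[i] = np.linalg.lstsq(A[i], b[i], rcond=None)[0]
            except np.linalg.LinAlgError:
                out[i] = 0.0
        return out


def _read_vtk_structured(path: str) -> tuple[np.ndarray, dict]:
    """Minimal legacy-ASCII VTK STRUCTURED_GRID reader (points + point data)."""
    with open(path) as fh:
        tokens = fh.read().split()
    tok = [t for t in tokens]
    lower = [t.lower() for t in tok]

    def find(word, start=0):
        try:
            return lower.index(word, start)
        except ValueError as exc:
            raise ValueError(f"malformed VTK file: missing {word!r}") from exc

    i = find("points")
    n_points = int(tok[i + 1])
    coords = np.array(tok[i + 3 : i + 3 + 3 * n_points], dtype=float)
    nodes = coords.reshape(n_points, 3)

    values: dict = {}
    j = find("point_data")
    pos = j + 2
    while pos < len(tok):
        kind = lower[pos]
        if kind == "scalars":
            name = tok[pos + 1]
            pos += 3
            if tok[pos].isdigit():  # optional component count
                pos += 1
            if lower[pos] == "lookup_table":
                pos += 2
            values[name] = np.array(tok[pos : pos + n_points], dtype=float)
            pos += n_points
        elif kind == "vectors":
            name = tok[pos + 1]
            pos += 3
            arr = np.array(tok[pos : pos + 3 * n_points], dtype=float)
            arr = arr.reshape(n_points, 3)
            values["u"], values["v"], values["w"] = arr[:, 0], arr[:, 1], arr[:, 2]
            pos += 3 * n_points
        else:
            pos += 1
    return nodes, values


def load_gridded_field(
    path: str,
    mode: str = "interpolated",
    fluid: FluidProperties = AIR,
    friction_velocity: float | None = None,
) -> GriddedField:
    """Load a structured-grid node file (columnar CSV or legacy-ASCII VTK).

    CSV files need columns ``x,y,z,u,v,w,k,omega,wall_distance``; VTK files
    need POINT_DATA scalars of the same names (velocity may be a VECTORS
    field).  ``mode`` selects cell-centered vs interpolated sampling.
    """
    path = str(path)
    if path.endswith((".vtk", ".vts")):
        nodes, values = _read_vtk_structured(path)
    else:
        frame = pd.read_csv(path)
        missing = [c for c in _GRID_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"gridded field file is missing columns {missing}")
        nodes = frame[["x", "y", "z"]].to_numpy(dtype=float)
        values = {
            c: frame[c].to_numpy(dtype=float) for c in _GRID_COLUMNS[3:]
        }
    return GriddedField(
        nodes, values, mode=mode, fluid=fluid, friction_velocity=friction_velocity
    )
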