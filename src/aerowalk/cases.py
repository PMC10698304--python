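"""Benchmark case definitions, model-feature presets, and the case runner.

The named presets encode the model-feature matrix explored in this
package: from plain mean-flow tracking (``no_dispersion``) through the
default isotropic discrete random walk, previously published near-wall
correction sets (``bass``, ``thomas``), the eddy-interaction-model
modifications (lifetime floor, variable interpolation, drift correction),
up to the ``recommended`` configuration that adds the correlated y+ limit
and, optionally, a physical NW limit (``recommended_nw<x>`` with x in
micrometers).

The turbulence base model and shear-flow-correction columns of the
feature matrix are flow-solver choices; they are recorded in presets for
provenance but have no effect here, because the flow field is an input.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import asdict, dataclass, field as dc_field

import numpy as np
import yaml

from . import __version__
from .deposition import Region, RegionMap
from .eim import CorrectionConfig
from .field_stats import (
    DEFAULT_SHELL_YPLUS,
    volume_average,
    yplus_limit_from_correlation,
)
from .flow_fields import (
    AIR,
    AnalyticPipeField,
    CurvedTubeField,
    FluidProperties,
)
from .particle_dynamics import (
    D2I_DIAMETERS_UM,
    VERTICAL_PIPE_DIAMETERS_UM,
    SizeDistribution,
    inject,
)
from .tracking import RunResult, track

__all__ = [
    "CaseConfig",
    "PRESETS",
    "resolve_preset",
    "make_vertical_pipe_case",
    "make_curved_tube_case",
    "run_case",
    "build_field",
    "build_region_map",
    "resolve_yplus_limits",
]

_STANDARD_GRAVITY = 9.81  # m/s^2

#: Model-feature matrix as named presets.
PRESETS: dict[str, dict] = {
    "no_dispersion": dict(
        base_model="lrn_kw", sfc=True,
        corrections=dict(dispersion=False, tl_plus_floor=None),
    ),
    "no_dispersion_sst": dict(
        base_model="lrn_kw_sst", sfc=None,
        corrections=dict(dispersion=False, tl_plus_floor=None),
    ),
    "default": dict(
        base_model="lrn_kw", sfc=True,
        corrections=dict(
            yplus_limit=0.0, nw_limit=0.0, interpolation="off",
            tl_plus_floor=None, drift_correction=False,
        ),
    ),
    "default_sst": dict(
        base_model="lrn_kw_sst", sfc=None,
        corrections=dict(
            yplus_limit=0.0, nw_limit=0.0, interpolation="off",
            tl_plus_floor=None, drift_correction=False,
        ),
    ),
    "bass": dict(
        base_model="lrn_kw", sfc=True,
        corrections=dict(
            yplus_limit=60.0, nw_limit=2e-6, interpolation="nw_only",
            tl_plus_floor=None, drift_correction=False,
        ),
    ),
    "thomas": dict(
        base_model="lrn_kw", sfc=False,
        corrections=dict(
            yplus_limit=60.0, nw_limit=0.0, interpolation="nw_only",
            tl_plus_floor=None, drift_correction=False,
        ),
    ),
    "eim_no_dc": dict(
        base_model="lrn_kw_sst", sfc=None,
        corrections=dict(
            yplus_limit=0.0, nw_limit=0.0, interpolation="everywhere",
            tl_plus_floor=3.0, drift_correction=False,
        ),
    ),
    "eim": dict(
        base_model="lrn_kw_sst", sfc=None,
        corrections=dict(
            yplus_limit=0.0, nw_limit=0.0, interpolation="everywhere",
            tl_plus_floor=3.0, drift_correction=True,
        ),
    ),
    "recommended": dict(
        base_model="lrn_kw_sst", sfc=None,
        corrections=dict(
            yplus_limit="correlated", nw_limit=0.0, interpolation="everywhere",
            tl_plus_floor=3.0, drift_correction=True,
        ),
    ),
}

_NW_PATTERN = re.compile(r"^recommended[_ ]?nw[l]?(\d+(?:\.\d+)?)$")


def resolve_preset(name: str) -> tuple[str, dict]:
    """Resolve a preset name (case/spacing-insensitive) to its settings.

    ``recommended_nw<x>`` presets add a NW limit of x micrometers to the
    recommended settings.
    """
    key = name.strip().lower().replace("-", "_").replace(" ", "_")
    m = _NW_PATTERN.match(key)
    if m:
        base = dict(PRESETS["recommended"])
        corr = dict(base["corrections"])
        corr["nw_limit"] = float(m.group(1)) * 1e-6
        base = dict(base, corrections=corr)
        return key, base
    if key not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; known: {sorted(PRESETS)} "
            "plus recommended_nw<x>"
        )
    return key, PRESETS[key]


@dataclass
class CaseConfig:
    """A fully resolved, runnable simulation case."""

    geometry: dict
    flow: dict
    injection: dict
    particle_density: float
    corrections: CorrectionConfig
    gravity: tuple = (0.0, 0.0, 0.0)
    preset: str | None = None
    base_model: str | None = None
    sfc: bool | None = None
    name: str = "case"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["corrections"] = asdict(self.corrections)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CaseConfig":
        d = dict(d)
        corr = d.pop("corrections", {})
        if not isinstance(corr, CorrectionConfig):
            corr = CorrectionConfig(**corr)
        d["gravity"] = tuple(d.get("gravity", (0.0, 0.0, 0.0)))
        return cls(corrections=corr, **d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "CaseConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_vertical_pipe_case(
    preset: str,
    particle_density: float,
    n_per_bin: int = 10_000,
    seed: int = 0,
    fluid: FluidProperties = AIR,
) -> CaseConfig:
    """Vertical straight-pipe benchmark: D = 1.27 cm, L = 102 cm,
    86.36 L/min (nominal Re = 10,000), seven size bins, trap walls,
    gravity aligned with the mean flow."""
    key, spec = resolve_preset(preset)
    corr = CorrectionConfig(**spec["corrections"])
    return CaseConfig(
        name=f"vertical_pipe[{key}]",
        geometry=dict(kind="pipe", diameter=0.0127, length=1.02),
        flow=dict(
            flow_rate=86.36e-3 / 60.0,   # m^3/s
            reynolds=10_000.0,
            fluid_density=fluid.density,
            fluid_viscosity=fluid.viscosity,
        ),
        injection=dict(
            diameters_um=list(VERTICAL_PIPE_DIAMETERS_UM),
            n_per_bin=n_per_bin,
            seed=seed,
        ),
        particle_density=particle_density,
        corrections=corr,
        gravity=(0.0, 0.0, _STANDARD_GRAVITY),
        preset=key,
        base_model=spec.get("base_model"),
        sfc=spec.get("sfc"),
    )


#: Default curved-tube size bins (um), spanning the impaction-relevant
#: Stokes-number range of the bend benchmark.
CURVED_TUBE_DIAMETERS_UM = (1.0, 1.5, 2.2, 3.2, 4.6, 6.8, 9.0)


def make_curved_tube_case(
    preset: str,
    particle_density: float,
    n_per_bin: int = 5_000,
    seed: int = 0,
    fluid: FluidProperties = AIR,
) -> CaseConfig:
    """90-degree bend benchmark: D = 5.03 mm, bend ratio 5.7 (bend radius
    over tube radius), inlet/outlet extensions of 10 diameters, inlet
    velocity 17.42 m/s (Re near 6,000), trap walls."""
    key, spec = resolve_preset(preset)
    corr = CorrectionConfig(**spec["corrections"])
    diameter = 5.03e-3
    return CaseConfig(
        name=f"curved_tube[{key}]",
        geometry=dict(
            kind="bend",
            diameter=diameter,
            bend_ratio=5.7,
            extension_lengths=10.0 * diameter,
        ),
        flow=dict(
            bulk_velocity=17.42,
            fluid_density=fluid.density,
            fluid_viscosity=fluid.viscosity,
        ),
        injection=dict(
            diameters_um=list(CURVED_TUBE_DIAMETERS_UM),
            n_per_bin=n_per_bin,
            seed=seed,
        ),
        particle_density=particle_density,
        corrections=corr,
        gravity=(0.0, 0.0, 0.0),
        preset=key,
        base_model=spec.get("base_model"),
        sfc=spec.get("sfc"),
    )


def build_field(config: CaseConfig):
    """Construct the analytic flow field for a case."""
    fluid = FluidProperties(
        config.flow.get("fluid_density", AIR.density),
        config.flow.get("fluid_viscosity", AIR.viscosity),
    )
    geo = config.geometry
    if geo["kind"] == "pipe":
        area = math.pi * geo["diameter"] ** 2 / 4.0
        if "flow_rate" in config.flow:
            bulk = config.flow["flow_rate"] / area
        else:
            bulk = config.flow["bulk_velocity"]
        return AnalyticPipeField(
            geo["diameter"], bulk, geo["length"], fluid=fluid,
            reynolds=config.flow.get("reynolds"),
        )
    if geo["kind"] == "bend":
        return CurvedTubeField(
            geo["diameter"], geo["bend_ratio"], geo["extension_lengths"],
            config.flow["bulk_velocity"], fluid=fluid,
            reynolds=config.flow.get("reynolds"),
        )
    raise ValueError(f"unknown geometry kind {geo['kind']!r}")


def build_region_map(config: CaseConfig, field_) -> RegionMap:
    geo = config.geometry
    if geo["kind"] == "pipe":
        return RegionMap([Region("pipe", "trap")], [geo["length"]], "filter")
    if geo["kind"] == "bend":
        l_ext = geo["extension_lengths"]
        arc = field_.bend_radius * math.pi / 2.0
        return RegionMap(
            [
                Region("inlet_extension", "trap"),
                Region("bend", "trap"),
                Region("outlet_extension", "trap"),
            ],
            [l_ext, l_ext + arc, l_ext + arc + l_ext],
            "filter",
        )
    raise ValueError(f"unknown geometry kind {geo['kind']!r}")


def resolve_yplus_limits(
    config: CaseConfig, field_, region_map: RegionMap
) -> np.ndarray:
    """Per-wall-region y+ limits, resolving the ``"correlated"`` setting
    against the field's near-wall volume statistics."""
    setting = config.corrections.yplus_limit
    n_wall = len(region_map.regions)
    if isinstance(setting, str):
        if setting != "correlated":
            raise ValueError(f"unknown yplus_limit setting {setting!r}")
        cells = field_.shell_cell_table()
        shell = volume_average(
            zip(cells["cell_re"], cells["volume"], cells["yplus"]),
            yplus_upper=DEFAULT_SHELL_YPLUS,
            quantity="cell_re",
        )
        limit = yplus_limit_from_correlation(shell.value, form="linear")
        return np.full(n_wall, limit)
    if isinstance(setting, dict):
        return np.array(
            [float(setting.get(r.name, 0.0)) for r in region_map.regions]
        )
    return np.full(n_wall, float(setting))


def run_case(config: CaseConfig, seed: int | None = None) -> RunResult:
    """Run a case end to end: build the field, inject, track, tally.

    Fully reproducible from (config, seed); ``seed`` overrides the seed
    stored in the injection block.  The result carries a manifest and a
    ``failed`` flag raised by mass-conservation violations or particles
    still suspended at the residence-time cap.
    """
    field_ = build_field(config)
    region_map = build_region_map(config, field_)
    limits = resolve_yplus_limits(config, field_, region_map)
    inj = config.injection
    psd = SizeDistribution.from_bins(
        inj["diameters_um"], inj.get("mass_weights")
    )
    run_seed = inj.get("seed", 0) if seed is None else seed
    particles = inject(
        field_, psd, inj["n_per_bin"], config.particle_density, run_seed
    )
    result = track(
        field_,
        particles,
        config.corrections,
        region_map,
        seed=run_seed,
        gravity=config.gravity,
        yplus_limits=limits,
        bin_diameters=[d * 1e-6 for d in inj["diameters_um"]],
    )
    failed = (
        result.tally.conservation_error() > 1e-9
        or result.stats["n_unfinished"] > 0
    )
    result.stats["failed"] = failed
    result.stats["yplus_limits"] = [float(x) for x in limits]
    result.stats["manifest"] = {
        "case": config.name,
        "preset": config.preset,
        "seed": int(run_seed),
        "version": __version__,
        "corrections": asdict(config.corrections),
        "n_per_bin": int(inj["n_per_bin"]),
    }
    return result


def write_outputs(result: RunResult, out_dir: str) -> None:
    """Serialise tally, per-bin table, and the run manifest to out_dir."""
    import pathlib

    from .deposition import tally_frame

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tally_frame(result.tally).to_csv(out / "tally.csv")
    result.per_bin.to_csv(out / "per_bin.csv")
    manifest = dict(result.stats)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
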