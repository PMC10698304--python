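"""Case presets, orchestration, and tracker-level physics properties."""

import math

import numpy as np
import pytest

from aerowalk.cases import (
    CaseConfig,
    make_curved_tube_case,
    make_vertical_pipe_case,
    resolve_preset,
    resolve_yplus_limits,
    build_field,
    build_region_map,
    run_case,
)
from aerowalk.deposition import Region, RegionMap, deposition_fraction
from aerowalk.eim import CorrectionConfig
from aerowalk.flow_fields import AnalyticPipeField, AnalyticProfile
from aerowalk.particle_dynamics import SizeDistribution, inject
from aerowalk.tracking import track

DENSITY = 920.0  # olive-oil-like benchmark aerosol


def small_pipe_case(preset, n_per_bin=60, diameters=(3.6, 7.2), seed=11):
    cfg = make_vertical_pipe_case(preset, particle_density=DENSITY,
                                  n_per_bin=n_per_bin, seed=seed)
    cfg.injection["diameters_um"] = list(diameters)
    return cfg


class TestPresets:
    def test_no_dispersion_preset(self):
        key, spec = resolve_preset("No Dispersion")
        assert spec["corrections"]["dispersion"] is False

    def test_recommended_preset_toggles(self):
        cfg = make_vertical_pipe_case("Recommended", particle_density=DENSITY)
        c = cfg.corrections
        assert c.interpolation == "everywhere"
        assert c.tl_plus_floor == 3.0
        assert c.drift_correction is True
        assert c.yplus_limit == "correlated"

    def test_recommended_nw5_adds_nw_limit(self):
        cfg = make_vertical_pipe_case("Recommended nw5", particle_density=DENSITY)
        assert cfg.corrections.nw_limit == pytest.approx(5e-6)

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            resolve_preset("garbage")

    def test_yaml_round_trip_preserves_toggles(self, tmp_path):
        cfg = make_vertical_pipe_case("recommended_nw5", particle_density=DENSITY)
        path = tmp_path / "case.yaml"
        cfg.to_yaml(path)
        back = CaseConfig.from_yaml(path)
        assert back.corrections == cfg.corrections
        assert back.geometry == cfg.geometry
        assert back.injection == cfg.injection
        assert back.gravity == cfg.gravity


class TestCaseFactories:
    def test_vertical_pipe_dimensions_and_bins(self):
        cfg = make_vertical_pipe_case("default", particle_density=DENSITY)
        assert cfg.geometry == dict(kind="pipe", diameter=0.0127, length=1.02)
        assert cfg.injection["diameters_um"] == [1.4, 2.5, 3.6, 5.3, 7.2, 10.1, 14.0]
        assert cfg.injection["n_per_bin"] == 10_000

    def test_curved_tube_geometry(self):
        cfg = make_curved_tube_case("thomas", particle_density=895.0)
        assert cfg.geometry["bend_ratio"] == 5.7
        assert cfg.geometry["extension_lengths"] == pytest.approx(10 * 5.03e-3)
        assert cfg.injection["n_per_bin"] == 5_000
        field = build_field(cfg)
        assert field.bend_radius == pytest.approx(5.7 * 5.03e-3 / 2)
        assert field.bulk_velocity == pytest.approx(17.42)

    def test_density_is_required(self):
        with pytest.raises(TypeError):
            make_vertical_pipe_case("default")  # no silent density default


class TestCorrelatedLimit:
    def test_resolved_limit_positive_for_pipe(self):
        cfg = make_vertical_pipe_case("recommended", particle_density=DENSITY)
        field = build_field(cfg)
        rm = build_region_map(cfg, field)
        limits = resolve_yplus_limits(cfg, field, rm)
        assert limits.shape == (1,)
        assert 1.0 < limits[0] < 20.0

    def test_scalar_and_dict_settings(self):
        cfg = make_vertical_pipe_case("bass", particle_density=DENSITY)
        field = build_field(cfg)
        rm = build_region_map(cfg, field)
        assert resolve_yplus_limits(cfg, field, rm)[0] == 60.0
        cfg.corrections = cfg.corrections.with_(yplus_limit={"pipe": 4.5})
        assert resolve_yplus_limits(cfg, field, rm)[0] == 4.5


class TestRunCase:
    def test_same_seed_identical_tallies(self):
        cfg = small_pipe_case("eim")
        a = run_case(cfg, seed=5)
        b = run_case(cfg, seed=5)
        assert a.tally.deposited == b.tally.deposited
        assert a.tally.entered == b.tally.entered
        assert (a.per_bin["DE_percent"] == b.per_bin["DE_percent"]).all()

    def test_mass_conservation_exact(self):
        res = run_case(small_pipe_case("recommended_nw5"), seed=3)
        t = res.tally
        assert t.released == pytest.approx(
            t.total_deposited + t.unfinished, rel=1e-12
        )
        assert res.stats["failed"] is False

    def test_df_sums_to_100(self):
        res = run_case(small_pipe_case("eim"), seed=4)
        total = sum(
            deposition_fraction(res.tally, r) for r in res.tally.region_names
        )
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_no_dispersion_is_deposition_free(self):
        cfg = small_pipe_case("no_dispersion", n_per_bin=40,
                              diameters=(1.4, 5.3, 14.0))
        res = run_case(cfg, seed=2)
        assert res.per_bin["DE_percent"].tolist() == [0.0, 0.0, 0.0]

    def test_manifest_records_provenance(self):
        res = run_case(small_pipe_case("eim", n_per_bin=20), seed=8)
        m = res.stats["manifest"]
        assert m["preset"] == "eim"
        assert m["seed"] == 8
        assert m["corrections"]["drift_correction"] is True


class TestTrackerPhysics:
    def _field(self, k_scale=1.0):
        prof = AnalyticProfile(
            k_peak_plus=4.5 * k_scale,
            k_log_plus=3.33 * k_scale,
            k_core_plus=0.8 * k_scale,
        )
        return AnalyticPipeField(0.0127, 11.36, 1.02, profile=prof)

    def _run(self, field, config, region_map=None, n=80, dia=(5.3,), seed=21):
        rm = region_map or RegionMap([Region("pipe", "trap")], [1.02], "filter")
        psd = SizeDistribution.from_bins(dia)
        parts = inject(field, psd, n, DENSITY, seed)
        return track(
            field, parts, config, rm, seed=seed, gravity=(0, 0, 9.81),
            yplus_limits=np.array([7.0]), bin_diameters=[d * 1e-6 for d in dia],
        )

    def test_dispersion_off_equals_zero_k_field(self):
        cfg_on = CorrectionConfig(dispersion=True, tl_plus_floor=3.0)
        cfg_off = CorrectionConfig(dispersion=False, tl_plus_floor=3.0)
        zero_k = self._field(k_scale=0.0)
        logs = {}
        for name, (field, cfg) in {
            "zero_k": (zero_k, cfg_on),
            "no_disp": (zero_k, cfg_off),
        }.items():
            rm = RegionMap([Region("pipe", "trap")], [1.02], "filter")
            psd = SizeDistribution.from_bins([5.3])
            parts = inject(field, psd, 10, DENSITY, 21)
            log = []
            track(field, parts, cfg, rm, seed=21, gravity=(0, 0, 9.81),
                  yplus_limits=np.array([7.0]), bin_diameters=[5.3e-6],
                  trace_particle=3, trace_log=log)
            logs[name] = log
        assert len(logs["zero_k"]) == len(logs["no_disp"])
        for a, b in zip(logs["zero_k"], logs["no_disp"]):
            assert a["yw"] == b["yw"]      # bit-identical trajectory
            assert a["vn"] == b["vn"]
            assert a["dt"] == b["dt"]

    def test_reflect_walls_lose_no_mass(self):
        field = self._field()
        rm = RegionMap([Region("pipe", "reflect")], [1.02], "filter")
        cfg = CorrectionConfig(dispersion=True, tl_plus_floor=3.0,
                               yplus_limit=7.0)
        res = self._run(field, cfg, region_map=rm, n=60)
        assert res.tally.deposited["pipe"] == 0.0
        assert res.tally.deposited["filter"] == pytest.approx(
            res.tally.released, rel=1e-12
        )

    def test_turbulence_scaling_does_not_decrease_deposition(self):
        cfg = CorrectionConfig(dispersion=True, tl_plus_floor=3.0,
                               yplus_limit=7.0, drift_correction=False)
        des = []
        for scale in (0.25, 1.0, 2.0):
            res = self._run(self._field(scale), cfg, n=150, dia=(5.3,))
            des.append(res.tally.deposited["pipe"])
        assert des[0] <= des[1] + 1e-12 <= des[2] + 1e-12

    def test_floored_timescale_never_below_bound(self):
        cfg = CorrectionConfig(dispersion=True, tl_plus_floor=3.0,
                               yplus_limit=7.0)
        res = self._run(self._field(), cfg, n=60)
        assert res.stats["min_tl_plus"] == pytest.approx(3.0, abs=1e-9)

    def test_curved_tube_big_particles_impact_more(self):
        cfg = make_curved_tube_case("eim", particle_density=895.0,
                                    n_per_bin=80, seed=6)
        cfg.injection["diameters_um"] = [1.0, 9.0]
        res = run_case(cfg, seed=6)
        de = res.per_bin["DE_percent"]
        assert de.iloc[1] > de.iloc[0]
        assert res.stats["failed"] is False
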