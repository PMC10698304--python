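"""Analytic duct fields and the gridded-field reader."""

import math

import numpy as np
import pytest

from aerowalk.flow_fields import (
    CurvedTubeField,
    DomainError,
    load_gridded_field,
    make_analytic_pipe_field,
    sample,
)

from conftest import PIPE_DIAMETER, PIPE_FLOW_RATE, PIPE_LENGTH


class TestAnalyticPipe:
    def test_bulk_velocity_from_flow_rate(self, pipe_field):
        # Q / (pi D^2 / 4) for the benchmark pipe
        assert pipe_field.bulk_velocity == pytest.approx(11.36, abs=0.01)

    def test_friction_velocity_blasius(self, pipe_field):
        # u* = U sqrt(f/8), f = 0.316 Re^(-1/4) at the nominal Re
        assert pipe_field.friction_velocity == pytest.approx(0.714, abs=0.001)

    def test_no_slip_and_no_fluctuation_at_wall(self, pipe_field):
        s = pipe_field.sample([pipe_field.radius, 0.0, 0.5])
        assert np.linalg.norm(s.mean_velocity) == pytest.approx(0.0, abs=1e-12)
        assert s.tke == pytest.approx(0.0, abs=1e-12)
        assert s.wall_distance == 0.0
        assert s.yplus == 0.0

    def test_centerline_velocity_is_area_mean_ratio(self, pipe_field):
        # area-average of the 1/7 profile: U_bulk/U_c = 49/60
        s = sample(pipe_field, [0.0, 0.0, 0.5])
        assert s.mean_velocity[2] == pytest.approx(
            60.0 / 49.0 * pipe_field.bulk_velocity, rel=1e-12
        )
        # independent oracle: numerical area integration of the profile
        r = np.linspace(0.0, pipe_field.radius, 40001)
        u = pipe_field.axial_speed(pipe_field.radius - r)
        u_bulk = np.trapezoid(u * 2 * np.pi * r, r) / (
            math.pi * pipe_field.radius**2
        )
        assert s.mean_velocity[2] == pytest.approx(60.0 / 49.0 * u_bulk, rel=1e-3)

    def test_mass_flow_recovered_within_half_percent(self, pipe_field):
        r = np.linspace(0.0, pipe_field.radius, 20001)
        u = pipe_field.axial_speed(pipe_field.radius - r)
        q = np.trapezoid(u * 2 * np.pi * r, r)
        assert q == pytest.approx(PIPE_FLOW_RATE, rel=5e-3)

    def test_yplus_definition_holds_at_every_sample(self, pipe_field):
        for frac in (0.01, 0.2, 0.7, 0.999):
            s = pipe_field.sample([frac * pipe_field.radius, 0.0, 0.1])
            expected = (
                s.wall_distance * s.friction_velocity * s.fluid_density
                / s.dynamic_viscosity
            )
            assert s.yplus == pytest.approx(expected, rel=1e-12)

    def test_sample_invariants(self, pipe_field):
        s = pipe_field.sample([0.003, 0.002, 0.9])
        assert s.tke >= 0 and s.sdr > 0
        assert np.linalg.norm(s.wall_normal) == pytest.approx(1.0)
        # sigma gradient points along the wall normal for an axisymmetric field
        g = s.sigma_gradient
        cross = np.cross(g / np.linalg.norm(g), s.wall_normal)
        assert np.linalg.norm(cross) == pytest.approx(0.0, abs=1e-9)

    def test_out_of_domain_raises(self, pipe_field):
        with pytest.raises(DomainError):
            pipe_field.sample([PIPE_DIAMETER, 0.0, 0.5])
        with pytest.raises(DomainError):
            pipe_field.sample([0.0, 0.0, 2 * PIPE_LENGTH])

    def test_non_turbulent_reynolds_rejected(self):
        with pytest.raises(ValueError, match="turbulent range"):
            make_analytic_pipe_field(0.0127, reynolds=1_000.0)
        with pytest.raises(ValueError):
            make_analytic_pipe_field(0.0127)  # neither Re nor flow rate

    def test_k_profile_peaks_in_buffer_layer(self, pipe_field):
        nu = pipe_field.fluid.kinematic_viscosity
        us = pipe_field.friction_velocity
        yplus = np.linspace(0.5, 300, 1200)
        kplus = pipe_field.tke(yplus * nu / us) / us**2
        peak_y = yplus[np.argmax(kplus)]
        assert 10 < peak_y < 20
        assert 4.0 < kplus.max() < 5.0
        assert kplus[-1] < kplus.max() / 3  # decays towards the core


@pytest.fixture(scope="module")
def bend():
    return CurvedTubeField(
        diameter=5.03e-3,
        bend_ratio=5.7,
        extension_lengths=10 * 5.03e-3,
        bulk_velocity=17.42,
    )


class TestCurvedTube:

    def test_bend_radius_is_ratio_times_tube_radius(self, bend):
        assert bend.bend_radius == pytest.approx(5.7 * 5.03e-3 / 2)

    def test_centerline_wall_distance_in_all_segments(self, bend):
        l1 = bend.extension_length
        rb = bend.bend_radius
        pts = [
            [0.0, 0.0, 0.5 * l1],                              # inlet
            [rb - rb / math.sqrt(2), 0.0, l1 + rb / math.sqrt(2)],  # mid-bend
            [rb + 0.5 * l1, 0.0, l1 + rb],                     # outlet
        ]
        _, yw, _, tangent = bend.local_coords(np.array(pts))
        assert yw == pytest.approx(bend.radius, rel=1e-9)
        assert tangent[0] == pytest.approx([0, 0, 1])
        assert tangent[1] == pytest.approx(
            [1 / math.sqrt(2), 0, 1 / math.sqrt(2)]
        )
        assert tangent[2] == pytest.approx([1, 0, 0])

    def test_arc_length_monotone_along_path(self, bend):
        l1 = bend.extension_length
        rb = bend.bend_radius
        phis = np.linspace(0, math.pi / 2, 9)
        pts = np.stack(
            [rb - rb * np.cos(phis), np.zeros_like(phis), l1 + rb * np.sin(phis)],
            axis=1,
        )
        s, _, _, _ = bend.local_coords(pts)
        assert np.all(np.diff(s) > 0)
        assert s[0] == pytest.approx(l1)
        assert s[-1] == pytest.approx(l1 + rb * math.pi / 2)


class TestGriddedField:
    def _write_grid(self, path, k_values, n=3):
        import pandas as pd

        xs, ys, zs = np.meshgrid(
            np.linspace(0, 1, n), np.linspace(0, 1, n), np.linspace(0, 1, n),
            indexing="ij",
        )
        df = pd.DataFrame(
            {
                "x": xs.ravel(), "y": ys.ravel(), "z": zs.ravel(),
                "u": 1.0, "v": 0.0, "w": 0.0,
                "k": k_values(xs.ravel(), ys.ravel(), zs.ravel()),
                "omega": 10.0,
                "wall_distance": ys.ravel(),
            }
        )
        df.to_csv(path, index=False)
        return path

    def test_constant_field_both_modes(self, tmp_path):
        p = self._write_grid(tmp_path / "g.csv", lambda x, y, z: 0.5)
        for mode in ("cell_centered", "interpolated"):
            f = load_gridded_field(p, mode=mode)
            s = f.sample([0.37, 0.41, 0.73])
            assert s.tke == pytest.approx(0.5, rel=1e-9)
            assert np.allclose(s.sigma_gradient, 0.0, atol=1e-9)

    def test_query_at_node_returns_node_value(self, tmp_path):
        p = self._write_grid(tmp_path / "g.csv", lambda x, y, z: 0.1 + x)
        f = load_gridded_field(p, mode="interpolated")
        s = f.sample([0.5, 0.5, 0.5])
        assert s.tke == pytest.approx(0.6, rel=1e-9)

    def test_two_node_midpoint_symmetric_average(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "x": [0.0, 1.0], "y": [0.0, 0.0], "z": [0.0, 0.0],
                "u": [1.0, 1.0], "v": 0.0, "w": 0.0,
                "k": [1.0, 3.0], "omega": 10.0, "wall_distance": [1.0, 1.0],
            }
        )
        p = tmp_path / "seg.csv"
        df.to_csv(p, index=False)
        f = load_gridded_field(p, mode="interpolated")
        assert f.sample([0.5, 0.0, 0.0]).tke == pytest.approx(2.0)

    def test_interpolated_continuous_cell_centered_piecewise(self, tmp_path):
        p = self._write_grid(tmp_path / "g.csv", lambda x, y, z: 1.0 + x, n=4)
        fi = load_gridded_field(p, mode="interpolated")
        eps = 1e-6
        a = fi.sample([0.40, 0.5, 0.5]).tke
        b = fi.sample([0.40 + eps, 0.5, 0.5]).tke
        assert abs(a - b) < 1e-3  # O(eps) continuity
        fc = load_gridded_field(p, mode="cell_centered")
        # two queries inside the same host cell share the node value
        a = fc.sample([0.30, 0.5, 0.5]).tke
        b = fc.sample([0.35, 0.5, 0.5]).tke
        assert a == b

    def test_missing_column_named_in_error(self, tmp_path):
        import pandas as pd

        pd.DataFrame({"x": [0.0], "y": [0.0], "z": [0.0]}).to_csv(
            tmp_path / "bad.csv", index=False
        )
        with pytest.raises(ValueError, match="missing columns"):
            load_gridded_field(tmp_path / "bad.csv")

    def test_vtk_structured_grid_reader(self, tmp_path):
        n = 8
        xs = np.linspace(0, 1, 2)
        pts = [(x, y, z) for z in xs for y in xs for x in xs]
        lines = [
            "# vtk DataFile Version 3.0", "synthetic grid", "ASCII",
            "DATASET STRUCTURED_GRID", "DIMENSIONS 2 2 2", f"POINTS {n} float",
        ]
        lines += [f"{p[0]} {p[1]} {p[2]}" for p in pts]
        lines += [f"POINT_DATA {n}", "SCALARS k float 1", "LOOKUP_TABLE default"]
        lines += ["0.5"] * n
        lines += ["SCALARS omega float 1", "LOOKUP_TABLE default"]
        lines += ["10.0"] * n
        lines += ["SCALARS wall_distance float 1", "LOOKUP_TABLE default"]
        lines += ["1.0"] * n
        lines += ["VECTORS velocity float"]
        lines += ["1.0 0.0 0.0"] * n
        path = tmp_path / "grid.vtk"
        path.write_text("\n".join(lines))
        f = load_gridded_field(str(path), mode="interpolated")
        s = f.sample([0.5, 0.5, 0.5])
        assert s.tke == pytest.approx(0.5)
        assert s.mean_velocity[0] == pytest.approx(1.0)
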