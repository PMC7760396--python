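"""Mesh/field containers, point location, fluxes, cross-sections and I/O."""

from __future__ import annotations

import numpy as np
import pytest

from tcpcflow.mesh_and_fields import (
    CrossSectionError,
    FieldSeriesError,
    PhysicalConstants,
    ScalarWaveform,
    boundary_flux,
    cross_section,
    locate_cell,
    locate_cell_brute,
    read_field_series,
    write_field_series,
)
from tcpcflow.synthetic_data import poiseuille_fixture


class TestPhysicalConstants:
    def test_defaults_are_blood_at_rest(self):
        c = PhysicalConstants()
        assert c.density == 1000.0
        assert c.kinematic_viscosity == 3.5e-6
        assert c.cycle_period == 0.86
        assert c.dynamic_viscosity == pytest.approx(3.5e-3)

    @pytest.mark.parametrize("field", ["density", "kinematic_viscosity", "cycle_period"])
    def test_rejects_nonpositive(self, field):
        with pytest.raises(ValueError):
            PhysicalConstants(**{field: 0.0})

    def test_pressure_unit_round_trip(self):
        c = PhysicalConstants()
        p = np.array([0.07, 0.87, 11.0])
        assert np.allclose(c.mmhg(c.pa(p)), p)


class TestScalarWaveform:
    def test_rejects_non_monotone_times(self):
        with pytest.raises(ValueError, match="non-monotone"):
            ScalarWaveform(np.array([0.0, 0.2, 0.1]), np.zeros(3))

    def test_rejects_length_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            ScalarWaveform(np.arange(3.0), np.zeros(2))
        with pytest.raises(ValueError):
            ScalarWaveform(np.array([]), np.array([]))

    def test_time_average_is_trapezoidal(self):
        t = np.linspace(0.0, 1.0, 1001)
        w = ScalarWaveform(t, np.sin(2 * np.pi * t))
        assert w.time_average() == pytest.approx(0.0, abs=1e-6)


class TestLocateCell:
    def test_centroid_gets_quarter_weights(self, coarse_mesh):
        c = 17
        centroid = coarse_mesh.points[coarse_mesh.cells[c]].mean(axis=0)
        hit = locate_cell(coarse_mesh, centroid)
        assert hit is not None
        cell, w = hit
        verts = set(coarse_mesh.cells[cell])
        assert verts == set(coarse_mesh.cells[c]) or cell == c
        assert np.allclose(np.sort(w), 0.25, atol=1e-9)

    def test_vertex_query_breaks_tie_to_lowest_incident_cell(self, coarse_mesh):
        node = int(coarse_mesh.cells[40, 0])
        p = coarse_mesh.points[node]
        hit = locate_cell(coarse_mesh, p)
        assert hit is not None
        cell, w = hit
        # weight concentrates on the queried vertex
        local = list(coarse_mesh.cells[cell]).index(node)
        assert w[local] == pytest.approx(1.0, abs=1e-9)
        # lowest incident cell index wins the tie (brute scans ascending)
        brute = locate_cell_brute(coarse_mesh, p)
        assert brute is not None and cell == brute[0]

    def test_point_far_outside_is_rejected(self, coarse_mesh):
        assert locate_cell(coarse_mesh, np.array([1.0, 1.0, 1.0])) is None

    def test_walk_with_hint_matches_brute_force(self, coarse_mesh):
        rng = np.random.default_rng(11)
        lo = coarse_mesh.points.min(axis=0)
        hi = coarse_mesh.points.max(axis=0)
        hint = 0
        for p in rng.uniform(lo, hi, size=(80, 3)):
            brute = locate_cell_brute(coarse_mesh, p)
            walked = locate_cell(coarse_mesh, p, hint=hint)
            if brute is None:
                assert walked is None
            else:
                assert walked is not None
                assert walked[0] == brute[0]
                np.testing.assert_allclose(walked[1], brute[1], atol=1e-9)
                hint = walked[0]


class TestBoundaryFlux:
    def test_zero_velocity_zero_flux(self, coarse_rigid_series):
        import copy

        fr = copy.deepcopy(coarse_rigid_series.frames[0])
        fr.velocity[:] = 0.0
        assert boundary_flux(coarse_rigid_series.mesh, fr, "FP") == 0.0

    def test_plug_flow_equals_area_times_speed(self, fine_pipe_fixture):
        mesh = fine_pipe_fixture.mesh
        fr = fine_pipe_fixture.frames[0]
        vel = np.zeros_like(fr.velocity)
        vel[:, 2] = 0.2
        from tcpcflow.mesh_and_fields import FieldFrame

        plug = FieldFrame(0.0, fr.node_positions, vel, fr.pressure)
        q = boundary_flux(mesh, plug, "FP")
        q_true = 0.2 * np.pi * 0.005**2 * 1e6  # U * pi R^2 in mL/s
        assert q == pytest.approx(q_true, rel=0.01)

    def test_poiseuille_flux_recovers_prescribed_flow(self, fine_pipe_fixture):
        fr = fine_pipe_fixture.frames[0]
        q_in = boundary_flux(fine_pipe_fixture.mesh, fr, "FP")
        q_out = boundary_flux(fine_pipe_fixture.mesh, fr, "LPA")
        assert q_in == pytest.approx(10.0, rel=0.01)
        assert q_out == pytest.approx(q_in, rel=1e-12)

    def test_unknown_patch_label(self, coarse_rigid_series):
        with pytest.raises(Exception, match="unknown patch"):
            boundary_flux(coarse_rigid_series.mesh, coarse_rigid_series.frames[0], "AORTA")

    def test_rigid_series_mass_closure(self, coarse_rigid_series):
        """Sum of inlet fluxes equals sum of outlet fluxes on rigid walls."""
        mesh = coarse_rigid_series.mesh
        mean_inflow = 45.0  # mL/s, configured FP+SVC means
        for fr in coarse_rigid_series.frames[::3]:
            net = (
                boundary_flux(mesh, fr, "FP")
                + boundary_flux(mesh, fr, "SVC")
                - boundary_flux(mesh, fr, "LPA")
                - boundary_flux(mesh, fr, "RPA")
            )
            assert abs(net) < 0.01 * mean_inflow


class TestCrossSection:
    def test_cylinder_cut_recovers_circle_area(self, pipe_fixture):
        cs = cross_section(
            pipe_fixture.mesh, pipe_fixture.frames[0], [0, 0, 0.0251], [0, 0, 1]
        )
        assert cs.area_cm2 == pytest.approx(np.pi * 0.5**2, rel=0.01)

    def test_plane_missing_branch_is_an_error(self, pipe_fixture):
        with pytest.raises(CrossSectionError, match="misses"):
            cross_section(
                pipe_fixture.mesh, pipe_fixture.frames[0], [0, 0, 1.0], [0, 0, 1], "FP"
            )

    def test_area_error_decreases_under_refinement(self):
        errors = []
        for h in (2.0, 1.5, 1.0):
            fx = poiseuille_fixture(0.5, 5.0, 10.0, edge_length_mm=h, n_frames=1)
            cs = cross_section(fx.mesh, fx.frames[0], [0, 0, 0.0251], [0, 0, 1])
            errors.append(abs(cs.area_cm2 - np.pi * 0.25))
        assert errors[0] > errors[1] > errors[2]

    def test_moving_wall_area_scales_by_dilation_squared(
        self, desk_config, fine_moving_series
    ):
        """At peak dilation the cut area scales by (1+eps)^2."""
        p0, n = desk_config.fp_probe_plane()
        frames = fine_moving_series.frames
        times = fine_moving_series.times
        k_peak = int(np.argmin(np.abs(times - desk_config.cycle_period / 4.0)))
        a0 = cross_section(fine_moving_series.mesh, frames[0], p0, n).area_cm2
        a1 = cross_section(fine_moving_series.mesh, frames[k_peak], p0, n).area_cm2
        s = np.sin(2 * np.pi * times[k_peak] / desk_config.cycle_period)
        factor = (1.0 + desk_config.wall_amplitude * s) ** 2
        assert a1 / a0 == pytest.approx(factor, rel=0.01)


class TestSeriesIO:
    @pytest.mark.parametrize("fmt", ["vtk", "vtu"])
    def test_round_trip_identity(self, coarse_moving_series, tmp_path, fmt):
        manifest = write_field_series(coarse_moving_series, tmp_path / fmt, fmt=fmt)
        back = read_field_series(manifest)
        assert back.n_frames == coarse_moving_series.n_frames
        assert back.period == coarse_moving_series.period
        np.testing.assert_allclose(back.mesh.points, coarse_moving_series.mesh.points)
        np.testing.assert_array_equal(back.mesh.cells, coarse_moving_series.mesh.cells)
        assert set(back.mesh.patch_labels()) == {"FP", "SVC", "LPA", "RPA", "WALL"}
        k = coarse_moving_series.n_frames // 2
        np.testing.assert_allclose(
            back.frames[k].velocity, coarse_moving_series.frames[k].velocity
        )
        np.testing.assert_allclose(
            back.frames[k].pressure, coarse_moving_series.frames[k].pressure
        )

    def test_rigid_series_writes_reference_positions(
        self, coarse_rigid_series, tmp_path
    ):
        manifest = write_field_series(coarse_rigid_series, tmp_path)
        back = read_field_series(manifest)
        for fr in back.frames:
            np.testing.assert_allclose(fr.node_positions, back.mesh.points)

    def test_shuffled_times_rejected(self, coarse_rigid_series, tmp_path):
        import yaml

        manifest = write_field_series(coarse_rigid_series, tmp_path)
        data = yaml.safe_load(manifest.read_text())
        data["frames"][0], data["frames"][1] = data["frames"][1], data["frames"][0]
        manifest.write_text(yaml.safe_dump(data))
        with pytest.raises(FieldSeriesError, match="non-monotone times"):
            read_field_series(manifest)

    def test_missing_frame_file_names_the_frame(self, coarse_rigid_series, tmp_path):
        manifest = write_field_series(coarse_rigid_series, tmp_path)
        (tmp_path / "frame_0001.vtk").unlink()
        with pytest.raises(FieldSeriesError, match="frame_0001"):
            read_field_series(manifest)

    def test_wrong_node_count_names_the_file(self, coarse_rigid_series, tmp_path):
        manifest = write_field_series(coarse_rigid_series, tmp_path)
        # truncate one frame to a different (valid) mesh -> node-count mismatch
        small = poiseuille_fixture(0.3, 1.0, 5.0, edge_length_mm=2.0, n_frames=1)
        from tcpcflow.mesh_and_fields import write_field_series as wfs

        wfs(small, tmp_path / "other")
        import shutil

        shutil.copy(tmp_path / "other" / "frame_0000.vtk", tmp_path / "frame_0002.vtk")
        with pytest.raises(FieldSeriesError, match="frame_0002"):
            read_field_series(manifest)

    def test_empty_series_rejected(self, coarse_mesh):
        from tcpcflow.mesh_and_fields import FieldSeries

        with pytest.raises(FieldSeriesError, match="at least one frame"):
            FieldSeries(mesh=coarse_mesh, frames=[], period=0.86)
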