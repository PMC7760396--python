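"""Lagrangian transport: seeding, advection, washout and HFD."""

from __future__ import annotations

import numpy as np
import pytest

from tcpcflow.mesh_and_fields import FieldFrame, FieldSeries, locate_cell
from tcpcflow.particle_tracking import (
    ACTIVE,
    EXITED,
    STRANDED,
    ParticleEnsemble,
    SeedingProtocol,
    advect,
    hfd,
    residence_stats,
    seed_particles,
)
from tcpcflow.synthetic_data import build_pipe_mesh, poiseuille_fixture


class TestSeedingProtocol:
    def test_full_study_protocol_arithmetic(self):
        """700 seeds/event every 1 ms over one 0.86 s cycle means 860
        events, i.e. 602,000 particles."""
        proto = SeedingProtocol()
        events = proto.event_times()
        assert events.size == 860
        assert events.size * 700 == 602_000

    def test_duration_equal_to_interval_is_single_event(self):
        proto = SeedingProtocol(seed_interval=0.01, seeding_duration=0.01)
        assert proto.event_times().size == 1

    @pytest.mark.parametrize(
        "kw", [{"seed_interval": 0.0}, {"seed_interval": 0.2, "seeding_duration": 0.1},
               {"horizon_cycles": -1.0}]
    )
    def test_invalid_protocols_rejected(self, kw):
        with pytest.raises(ValueError):
            SeedingProtocol(**kw)

    def test_every_seed_is_locatable_at_its_seed_time(self, desk_rigid_series):
        proto = SeedingProtocol.desk_scale(seed=1, seed_interval=0.2)
        ens = seed_particles(desk_rigid_series, proto)
        assert np.all(ens.cell >= 0)
        for k in range(0, ens.n, 7):
            pos_t, _ = desk_rigid_series.sample(float(ens.seed_time[k]))
            hit = locate_cell(desk_rigid_series.mesh, ens.position[k], positions=pos_t)
            assert hit is not None

    def test_seed_count_is_events_times_points(self, desk_rigid_series):
        proto = SeedingProtocol.desk_scale(seed=0, seed_interval=0.1, seeds_per_event=10)
        ens = seed_particles(desk_rigid_series, proto)
        assert ens.n == proto.event_times().size * 10


class TestAdvection:
    def test_uniform_flow_exit_times_are_exact(self, uniform_flow_series):
        """In plug flow U z the exit time is (L - z0)/U."""
        proto = SeedingProtocol(seed_interval=0.01, seeding_duration=0.01,
                                seeds_per_event=12, seed=2)
        ens = seed_particles(uniform_flow_series, proto)
        z0 = ens.seed_position[:, 2].copy()
        ens = advect(ens, uniform_flow_series, substep=1e-3, horizon_cycles=2)
        assert np.all(ens.state == EXITED)
        assert set(ens.exit_patch.tolist()) == {"LPA"}
        expected = (0.05 - z0) / 0.1
        np.testing.assert_allclose(ens.exit_time, expected, atol=1e-8)

    def test_rigid_rotation_conserves_radius(self):
        """A solid-body rotation field (linear, hence interpolated exactly)
        keeps each particle's radius constant over a revolution."""
        mesh = build_pipe_mesh(0.5, 1.0, edge_length_mm=1.5)
        om = 2 * np.pi  # one revolution per second
        vel = np.zeros_like(mesh.points)
        vel[:, 0] = -om * mesh.points[:, 1]
        vel[:, 1] = om * mesh.points[:, 0]
        frames = [FieldFrame(t, mesh.points, vel, np.zeros(mesh.n_nodes))
                  for t in (0.0, 1.0)]
        series = FieldSeries(mesh=mesh, frames=frames, period=1.0)
        start = np.array([[0.003, 0.0, 0.005]])
        ens = ParticleEnsemble(
            seed_time=np.zeros(1), seed_position=start, position=start.copy(),
            cell=np.array([locate_cell(mesh, start[0])[0]]),
            state=np.array([ACTIVE], dtype=np.int8),
            exit_time=np.full(1, np.nan), exit_patch=np.array([None], dtype=object),
        )
        ens = advect(ens, series, substep=1e-3, horizon_cycles=1.0)
        r = np.hypot(ens.position[0, 0], ens.position[0, 1])
        assert abs(r - 0.003) / 0.003 < 1e-6

    def test_poiseuille_residence_matches_local_transit_time(self, pipe_fixture):
        """Seeds at cross-section nodes ride the exact nodal profile, so the
        residence time is L/u(r) to well under 0.1%."""
        proto = SeedingProtocol(seed_interval=0.01, seeding_duration=0.01, seed=1)
        ens = seed_particles(pipe_fixture, proto)
        ens = advect(ens, pipe_fixture, substep=1e-3, horizon_cycles=15)
        exited = ens.state == EXITED
        assert exited.mean() > 0.99
        R, L, Q = 0.005, 0.05, 10e-6
        r = np.hypot(ens.seed_position[:, 0], ens.seed_position[:, 1])
        u = 2 * Q / (np.pi * R * R) * (1 - (r / R) ** 2)
        expected = (L - ens.seed_position[:, 2]) / u
        err = np.abs(ens.residence_time[exited] - expected[exited]) / expected[exited]
        assert err.max() < 1e-3

    def test_substep_halving_convergence(self, pipe_fixture):
        proto = SeedingProtocol(seed_interval=0.01, seeding_duration=0.01,
                                seeds_per_event=15, seed=4)
        t1 = advect(seed_particles(pipe_fixture, proto), pipe_fixture,
                    substep=2e-3, horizon_cycles=10).exit_time
        t2 = advect(seed_particles(pipe_fixture, proto), pipe_fixture,
                    substep=1e-3, horizon_cycles=10).exit_time
        assert np.nanmax(np.abs(t1 - t2) / t2) < 1e-4

    def test_walking_and_brute_force_locators_agree(self):
        """On a small mesh, exhaustive-search tracking equals the walking
        tracker particle-for-particle."""
        fx = poiseuille_fixture(0.4, 2.0, 8.0, edge_length_mm=1.5, n_frames=1)
        assert fx.mesh.n_cells <= 5000
        proto = SeedingProtocol(seed_interval=0.01, seeding_duration=0.01, seed=5)
        a = advect(seed_particles(fx, proto), fx, substep=1e-3,
                   horizon_cycles=10, locator="walking")
        b = advect(seed_particles(fx, proto), fx, substep=1e-3,
                   horizon_cycles=10, locator="brute")
        np.testing.assert_array_equal(a.state, b.state)
        assert all(x == y for x, y in zip(a.exit_patch, b.exit_patch))
        np.testing.assert_allclose(a.exit_time, b.exit_time, atol=1e-9)

    def test_oversized_substep_rejected(self, desk_rigid_series):
        proto = SeedingProtocol.desk_scale(seed_interval=0.2)
        ens = seed_particles(desk_rigid_series, proto)
        with pytest.raises(ValueError, match="substep"):
            advect(ens, desk_rigid_series, substep=0.5)

    def test_particle_count_conserved(self, tracked_symmetric):
        c = tracked_symmetric.counts()
        assert c["active"] + c["exited"] + c["stranded"] == tracked_symmetric.n


def _fabricated_ensemble(exit_times, exit_patches, seed_times=None, extra_stranded=0):
    n = len(exit_times) + extra_stranded
    seed_time = np.zeros(n) if seed_times is None else np.asarray(seed_times, float)
    state = np.concatenate(
        [np.full(len(exit_times), EXITED, dtype=np.int8),
         np.full(extra_stranded, STRANDED, dtype=np.int8)]
    )
    ens = ParticleEnsemble(
        seed_time=seed_time,
        seed_position=np.zeros((n, 3)),
        position=np.zeros((n, 3)),
        cell=np.zeros(n, dtype=np.int64),
        state=state,
        exit_time=np.concatenate([np.asarray(exit_times, float),
                                  np.full(extra_stranded, np.nan)]),
        exit_patch=np.array(list(exit_patches) + [None] * extra_stranded, dtype=object),
        advected=True,
    )
    return ens


class TestResidenceStats:
    def test_washout_time_is_the_95th_exit(self):
        ens = _fabricated_ensemble(np.arange(1.0, 101.0), ["LPA"] * 100)
        r = residence_stats(ens, bin_width_s=1.0, cycle_period=0.86)
        assert r.w95_s == pytest.approx(95.0)
        assert r.w95_cycles == pytest.approx(95.0 / 0.86)
        assert r.counts.sum() == r.n_exited

    def test_plug_flow_washout_is_seeding_end_plus_transit(self, uniform_flow_series):
        proto = SeedingProtocol(seed_interval=0.02, seeding_duration=0.2,
                                seeds_per_event=10, seed=7)
        ens = seed_particles(uniform_flow_series, proto)
        substep = 1e-3
        ens = advect(ens, uniform_flow_series, substep=substep, horizon_cycles=3)
        r = residence_stats(ens, cycle_period=0.86)
        assert r.reached
        z0 = ens.seed_position[0, 2]
        expected = (proto.seeding_duration - proto.seed_interval) + (0.05 - z0) / 0.1
        assert abs(r.w95_s - expected) <= substep + 1e-12

    def test_unreached_washout_is_flagged_with_fraction(self):
        ens = _fabricated_ensemble(np.arange(1.0, 91.0), ["LPA"] * 90,
                                   extra_stranded=10)
        r = residence_stats(ens, cycle_period=0.86)
        assert not r.reached
        assert r.w95_s is None
        assert r.flag() == "washout not reached (90.0%)"

    def test_conservation_in_report(self, tracked_symmetric):
        r = residence_stats(tracked_symmetric, cycle_period=0.86)
        assert r.n_exited + r.n_stranded == tracked_symmetric.n


class TestHFD:
    def test_all_lpa_gives_hundred_percent(self):
        ens = _fabricated_ensemble([1.0, 2.0, 3.0], ["LPA"] * 3)
        assert hfd(ens).time_averaged_percent == 100.0

    def test_constructed_fates_nineteen_percent(self):
        """19 of 100 lung-bound particles to the LPA is an HFD of 19%."""
        patches = ["LPA"] * 19 + ["RPA"] * 81
        ens = _fabricated_ensemble(np.arange(1.0, 101.0), patches)
        assert hfd(ens).time_averaged_percent == pytest.approx(19.0)

    def test_lpa_and_rpa_shares_sum_to_hundred(self, tracked_symmetric):
        h = hfd(tracked_symmetric)
        assert h.time_averaged_percent + h.rpa_percent == pytest.approx(100.0)
        assert np.all((h.instantaneous.values >= 0) & (h.instantaneous.values <= 100))

    def test_caval_backflow_excluded_from_denominator(self):
        patches = ["LPA"] * 10 + ["RPA"] * 10 + ["FP"] * 5
        ens = _fabricated_ensemble(np.arange(1.0, 26.0), patches)
        assert hfd(ens).time_averaged_percent == pytest.approx(50.0)
        # but the caval exits still count for washout
        r = residence_stats(ens, cycle_period=0.86)
        assert r.n_exited == 25

    def test_no_pa_exits_is_an_error(self):
        ens = _fabricated_ensemble([1.0], ["FP"])
        with pytest.raises(ValueError, match="pulmonary"):
            hfd(ens)

    def test_symmetric_junction_splits_evenly(self, tracked_symmetric):
        """With equal PA radii, centered junction and a 50/50 outflow split,
        the hepatic flow distribution is 50% within the binomial 3-sigma
        band at the tracked particle count."""
        h = hfd(tracked_symmetric)
        n = h.n_lpa + h.n_rpa
        assert n > 300
        three_sigma = 3.0 * 100.0 * np.sqrt(0.25 / n)
        assert abs(h.time_averaged_percent - 50.0) < three_sigma


class TestRigidVsCompliantTransport:
    def test_compliant_washout_not_slower_than_rigid(
        self, tracked_symmetric, tracked_moving
    ):
        """Wall motion re-suspends near-wall particles, so the compliant
        run washes out at least as fast as the rigid one (W95 ordering when
        both reach 95%, exited-fraction ordering otherwise)."""
        r_rigid = residence_stats(tracked_symmetric, cycle_period=0.86)
        r_mov = residence_stats(tracked_moving, cycle_period=0.86)
        if r_rigid.reached and r_mov.reached:
            assert r_mov.w95_s <= r_rigid.w95_s
        else:
            assert r_mov.achieved_fraction >= r_rigid.achieved_fraction
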