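"""Shared fixtures: small synthetic geometries and field series.

Everything is generated at run time; session scope keeps the heavier
meshes/series built once.
"""

from __future__ import annotations

import numpy as np
import pytest

from tcpcflow.mesh_and_fields import FieldFrame, FieldSeries
from tcpcflow.synthetic_data import (
    SyntheticConfig,
    build_idealized_tcpc,
    build_pipe_mesh,
    make_field_series,
    poiseuille_fixture,
)


@pytest.fixture(scope="session")
def coarse_config() -> SyntheticConfig:
    """Coarse TCPC for fast structural tests (~4k cells)."""
    return SyntheticConfig(edge_length_mm=3.0, frame_interval=0.05)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_config):
    return build_idealized_tcpc(coarse_config)


@pytest.fixture(scope="session")
def coarse_rigid_series(coarse_config, coarse_mesh):
    return make_field_series(coarse_mesh, coarse_config, "rigid")


@pytest.fixture(scope="session")
def coarse_moving_series(coarse_config, coarse_mesh):
    return make_field_series(coarse_mesh, coarse_config, "moving")


@pytest.fixture(scope="session")
def desk_config() -> SyntheticConfig:
    """Desk-scale TCPC used by the particle-transport tests (~9k cells)."""
    return SyntheticConfig(edge_length_mm=2.5, frame_interval=0.02)


@pytest.fixture(scope="session")
def desk_mesh(desk_config):
    return build_idealized_tcpc(desk_config)


@pytest.fixture(scope="session")
def desk_rigid_series(desk_config, desk_mesh):
    return make_field_series(desk_mesh, desk_config, "rigid")


@pytest.fixture(scope="session")
def desk_moving_series(desk_config, desk_mesh):
    return make_field_series(desk_mesh, desk_config, "moving")


@pytest.fixture(scope="session")
def fine_moving_series(desk_mesh, desk_config):
    """Densely sampled moving series for waveform-shape assertions."""
    import dataclasses

    cfg = dataclasses.replace(desk_config, frame_interval=0.01)
    return make_field_series(desk_mesh, cfg, "moving")


@pytest.fixture(scope="session")
def pipe_fixture():
    """Poiseuille pipe at moderate resolution (R=0.5 cm, L=5 cm, Q=10 mL/s)."""
    return poiseuille_fixture(0.5, 5.0, 10.0, edge_length_mm=1.0)


@pytest.fixture(scope="session")
def fine_pipe_fixture():
    """Fine Poiseuille pipe for the 1% flux/power oracles."""
    return poiseuille_fixture(0.5, 5.0, 10.0, edge_length_mm=0.5)


@pytest.fixture(scope="session")
def tracked_symmetric(desk_rigid_series):
    """Desk-scale tracked ensemble on the symmetric junction (rigid)."""
    from tcpcflow.particle_tracking import SeedingProtocol, advect, seed_particles

    proto = SeedingProtocol.desk_scale(seed=3)
    ens = seed_particles(desk_rigid_series, proto)
    return advect(ens, desk_rigid_series, substep=2e-3, horizon_cycles=5)


@pytest.fixture(scope="session")
def tracked_moving(desk_moving_series):
    """Same protocol on the moving-wall companion series."""
    from tcpcflow.particle_tracking import SeedingProtocol, advect, seed_particles

    proto = SeedingProtocol.desk_scale(seed=3)
    ens = seed_particles(desk_moving_series, proto)
    return advect(ens, desk_moving_series, substep=2e-3, horizon_cycles=5)


@pytest.fixture(scope="session")
def uniform_flow_series():
    """Plug flow U = 0.1 m/s along a straight pipe (exact transit times)."""
    mesh = build_pipe_mesh(0.5, 5.0, edge_length_mm=1.5)
    vel = np.zeros_like(mesh.points)
    vel[:, 2] = 0.1
    pres = np.zeros(mesh.n_nodes)
    frames = [FieldFrame(t, mesh.points, vel, pres) for t in (0.0, 0.86)]
    return FieldSeries(mesh=mesh, frames=frames, period=0.86)
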