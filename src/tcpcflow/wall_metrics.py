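"""Wall-deformation metrics: area waveforms, deformation index, net-flow
volume integration and compliance estimation.

The deformation index DI = (A_max - A_min)/A_mean x 100% quantifies the
cyclic change of a vessel's cross-sectional area; the TCPC compliance
estimate divides the maximum cyclic volume change (from trapezoidal
integration of the net inflow-outflow) by the maximum change of the
volume-averaged pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .mesh_and_fields import (
    CAP_PATCHES,
    FieldSeries,
    ScalarWaveform,
    boundary_flux,
    cross_section,
)

__all__ = [
    "DeformationIndexResult",
    "ComplianceEstimate",
    "area_waveform",
    "deformation_index",
    "net_flow_waveform",
    "volume_waveform",
    "volume_averaged_pressure",
    "estimate_compliance",
]


@dataclass(frozen=True)
class DeformationIndexResult:
    """Extrema, mean and deformation index of an area waveform (cm², %)."""

    a_max: float
    a_min: float
    a_mean: float
    di_percent: float

    def __str__(self) -> str:  # one decimal, as reported clinically
        return (
            f"A_max={self.a_max:.2f} cm², A_min={self.a_min:.2f} cm², "
            f"A_mean={self.a_mean:.2f} cm², DI={self.di_percent:.1f}%"
        )


@dataclass(frozen=True)
class ComplianceEstimate:
    """Cyclic volume change, pressure change and compliance C = dV/dP."""

    dv_max_ml: float
    dp_max_mmhg: float
    compliance_ml_per_mmhg: float


def area_waveform(series: FieldSeries, plane_point, plane_normal,
                  branch: str | None = None) -> ScalarWaveform:
    """Cross-sectional area (cm²) of one branch at every stored frame.

    The cut is evaluated on each frame's node positions, so a moving wall
    yields a time-varying area while a rigid series gives a constant one.
    """
    areas = [
        cross_section(series.mesh, fr, plane_point, plane_normal, branch).area_cm2
        for fr in series.frames
    ]
    return ScalarWaveform(series.times, np.asarray(areas), unit="cm^2")


def deformation_index(areas: ScalarWaveform) -> DeformationIndexResult:
    """Deformation index of an area waveform.

    DI = (A_max - A_min) / A_mean x 100%, with A_mean the arithmetic mean
    of the samples.  Scale-invariant; zero for a constant waveform.
    """
    if len(areas) == 0:
        raise ValueError("empty area waveform")
    a_mean = areas.mean()
    if not a_mean > 0:
        raise ValueError(f"non-positive mean area ({a_mean:.3g} cm²)")
    a_max, a_min = areas.vmax, areas.vmin
    return DeformationIndexResult(
        a_max=a_max,
        a_min=a_min,
        a_mean=a_mean,
        di_percent=(a_max - a_min) / a_mean * 100.0,
    )


def net_flow_waveform(series: FieldSeries) -> ScalarWaveform:
    """Net flow (total inflow - total outflow, mL/s) at every frame.

    Zero (to mass-closure tolerance) for rigid walls; equals the cavity
    volume rate dV/dt for a deforming wall.
    """
    mesh = series.mesh
    for cap in CAP_PATCHES:
        mesh._require_patch(cap)
    net = []
    for fr in series.frames:
        q_in = sum(boundary_flux(mesh, fr, p) for p in CAP_PATCHES
                   if mesh.patch_kinds[p] == "inlet")
        q_out = sum(boundary_flux(mesh, fr, p) for p in CAP_PATCHES
                    if mesh.patch_kinds[p] == "outlet")
        net.append(q_in - q_out)
    return ScalarWaveform(series.times, np.asarray(net), unit="mL/s")


def volume_waveform(net_flow: ScalarWaveform, v0_ml: float) -> ScalarWaveform:
    """Cavity volume V(t) (mL) by trapezoidal integration of the net flow,
    with V(t0) = v0_ml."""
    v = v0_ml + cumulative_trapezoid(net_flow.values, net_flow.times, initial=0.0)
    return ScalarWaveform(net_flow.times, v, unit="mL")


def volume_averaged_pressure(series: FieldSeries) -> ScalarWaveform:
    """Pressure averaged over the cavity volume (mmHg) at every frame.

    Nodal pressures are cell-volume weighted: each tetrahedron contributes
    its volume times the mean of its four nodal values.
    """
    from .mesh_and_fields import _tet_volumes

    mesh = series.mesh
    const = np.empty(series.n_frames)
    for k, fr in enumerate(series.frames):
        vols = _tet_volumes(fr.node_positions, mesh.cells)
        pcell = fr.pressure[mesh.cells].mean(axis=1)
        const[k] = np.sum(vols * pcell) / np.sum(vols)
    return ScalarWaveform(series.times, const / 133.322, unit="mmHg")


def estimate_compliance(volume: ScalarWaveform,
                        pressure: ScalarWaveform) -> ComplianceEstimate:
    """Compliance C = (max V - min V) / (max P - min P) in mL/mmHg.

    ``volume`` in mL, ``pressure`` the volume-averaged cavity pressure in
    mmHg.  A constant volume gives C = 0; a zero pressure range is an error.
    """
    dv = volume.vrange
    dp = pressure.vrange
    if dp <= 0.0:
        raise ValueError("zero pressure range: compliance undefined")
    return ComplianceEstimate(
        dv_max_ml=dv, dp_max_mmhg=dp, compliance_ml_per_mmhg=dv / dp
    )
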