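"""Pressure drop, control-volume power loss and rigid-vs-compliant report
differencing.

Power loss is the net mechanical-energy flux into the control volume
bounded by the four vessel caps,

    PL = - sum over caps of  integral (p + 1/2 rho |v|^2) (v . n_out) dA,

the standard efficiency surrogate for cavopulmonary connections.  It is a
signed instantaneous quantity and may be negative under pulsatile flow
(energy temporarily returned by the flow).  Pressure drop is the
area-averaged static pressure difference between two caps (FP to LPA by
convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_and_fields import (
    CAP_PATCHES,
    MW_PER_W,
    FieldFrame,
    FieldSeries,
    PhysicalConstants,
    ScalarWaveform,
    UnstructuredMesh,
)

__all__ = [
    "HemoReport",
    "MetricSummary",
    "pressure_drop",
    "power_loss",
    "pressure_drop_waveform",
    "power_loss_waveform",
    "summarize",
    "compare_reports",
]


def _area_averaged(mesh: UnstructuredMesh, frame: FieldFrame, patch: str,
                   nodal: np.ndarray) -> float:
    """Facet-area-weighted average of a nodal scalar over a patch."""
    faces = mesh.patch_faces(patch)
    pos = frame.node_positions
    a, b, c = (pos[faces[:, i]] for i in range(3))
    areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    fmean = nodal[faces].mean(axis=1)
    return float(np.sum(areas * fmean) / np.sum(areas))


def pressure_drop(
    mesh: UnstructuredMesh,
    frame: FieldFrame,
    from_patch: str = "FP",
    to_patch: str = "LPA",
    constants: PhysicalConstants = PhysicalConstants(),
    total: bool = False,
) -> float:
    """Static pressure drop between two caps in mmHg.

    Area-averaged static pressure on ``from_patch`` minus ``to_patch``.
    With ``total=True`` the dynamic head 1/2 rho |v|^2 is included
    (total-pressure drop), offered as an optional variant.
    """
    mesh._require_patch(from_patch)
    mesh._require_patch(to_patch)
    nodal = frame.pressure
    if total:
        nodal = nodal + 0.5 * constants.density * np.einsum(
            "ij,ij->i", frame.velocity, frame.velocity
        )
    dp = _area_averaged(mesh, frame, from_patch, nodal) - _area_averaged(
        mesh, frame, to_patch, nodal
    )
    return dp / constants.pa_per_mmhg


def power_loss(
    mesh: UnstructuredMesh,
    frame: FieldFrame,
    constants: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Instantaneous control-volume power loss in mW.

    Net flux of static-plus-kinetic energy through the cap patches; the
    integrand (p + 1/2 rho |v|^2)(v . n_out) is quadratic-times-linear in
    the nodal fields and is integrated with the edge-midpoint rule, exact
    for quadratics on each facet.
    """
    pos = frame.node_positions
    rho = constants.density
    energy = frame.pressure + 0.5 * rho * np.einsum(
        "ij,ij->i", frame.velocity, frame.velocity
    )
    caps = [p for p in mesh.patch_labels() if mesh.patch_kinds[p] != "wall"]
    pl = 0.0
    for patch in caps:
        faces = mesh.patch_faces(patch)
        a, b, c = (pos[faces[:, i]] for i in range(3))
        nvec = 0.5 * np.cross(b - a, c - a)  # area-weighted outward normal
        area = np.linalg.norm(nvec, axis=1)
        nhat = nvec / area[:, None]
        # edge-midpoint values of the P1 fields
        ev = energy[faces]
        vv = frame.velocity[faces]
        flux = 0.0
        for i, j in ((0, 1), (1, 2), (0, 2)):
            em = 0.5 * (ev[:, i] + ev[:, j])
            vm = 0.5 * (vv[:, i] + vv[:, j])
            flux = flux + em * np.einsum("ij,ij->i", vm, nhat)
        pl -= np.sum(area * flux / 3.0)
    return float(pl) * MW_PER_W


def pressure_drop_waveform(series: FieldSeries, from_patch: str = "FP",
                           to_patch: str = "LPA",
                           constants: PhysicalConstants = PhysicalConstants(),
                           ) -> ScalarWaveform:
    """Pressure drop (mmHg) at every stored frame."""
    vals = [pressure_drop(series.mesh, fr, from_patch, to_patch, constants)
            for fr in series.frames]
    return ScalarWaveform(series.times, np.asarray(vals), unit="mmHg")


def power_loss_waveform(series: FieldSeries,
                        constants: PhysicalConstants = PhysicalConstants(),
                        ) -> ScalarWaveform:
    """Power loss (mW) at every stored frame."""
    vals = [power_loss(series.mesh, fr, constants) for fr in series.frames]
    return ScalarWaveform(series.times, np.asarray(vals), unit="mW")


@dataclass(frozen=True)
class MetricSummary:
    """Minimum, maximum and trapezoidal time average of one waveform."""

    minimum: float
    maximum: float
    average: float

    def __post_init__(self) -> None:
        if not (self.minimum - 1e-12 <= self.average <= self.maximum + 1e-12):
            raise ValueError("summary violates min <= average <= max")

    @property
    def fluctuation(self) -> float:
        """Peak-to-peak range max - min."""
        return self.maximum - self.minimum


@dataclass
class HemoReport:
    """Per-condition hemodynamic report: pressure-drop and power-loss
    waveforms with their extrema and cycle averages."""

    label: str
    pressure_drop: ScalarWaveform | None
    power_loss: ScalarWaveform | None
    pressure_drop_summary: MetricSummary
    power_loss_summary: MetricSummary

    @classmethod
    def from_summaries(
        cls,
        label: str,
        pressure_drop_mmhg: tuple[float, float, float],
        power_loss_mw: tuple[float, float, float],
    ) -> "HemoReport":
        """Build a report directly from (min, max, average) triples, e.g.
        when comparing against published table values."""
        return cls(
            label=label,
            pressure_drop=None,
            power_loss=None,
            pressure_drop_summary=MetricSummary(*pressure_drop_mmhg),
            power_loss_summary=MetricSummary(*power_loss_mw),
        )

    @property
    def metrics(self) -> dict[str, MetricSummary]:
        return {
            "pressure_drop_mmhg": self.pressure_drop_summary,
            "power_loss_mw": self.power_loss_summary,
        }


def _summary(wf: ScalarWaveform, period: float, require_full_cycle: bool) -> MetricSummary:
    span = wf.times[-1] - wf.times[0]
    if require_full_cycle and span < period * (1.0 - 1e-9):
        raise ValueError(
            f"waveform spans {span:.4g} s, less than one full cycle "
            f"({period:.4g} s); pass require_full_cycle=False for a partial summary"
        )
    return MetricSummary(minimum=wf.vmin, maximum=wf.vmax, average=wf.time_average())


def summarize(
    pressure_drop_wf: ScalarWaveform,
    power_loss_wf: ScalarWaveform,
    period: float,
    label: str = "",
    require_full_cycle: bool = True,
) -> HemoReport:
    """Summarize metric waveforms over whole cycles.

    Extrema are taken over the samples; the average is the trapezoidal time
    average.  A waveform covering less than one full cycle is rejected
    unless explicitly flagged as partial.
    """
    return HemoReport(
        label=label,
        pressure_drop=pressure_drop_wf,
        power_loss=power_loss_wf,
        pressure_drop_summary=_summary(pressure_drop_wf, period, require_full_cycle),
        power_loss_summary=_summary(power_loss_wf, period, require_full_cycle),
    )


def compare_reports(a: HemoReport, b: HemoReport) -> dict[str, dict[str, float]]:
    """Difference table between two hemodynamic reports.

    For each metric: the absolute difference of the time averages and the
    per-report fluctuation ranges (max - min) with their difference.
    """
    if set(a.metrics) != set(b.metrics):
        raise ValueError(
            f"mismatched metric sets: {sorted(a.metrics)} vs {sorted(b.metrics)}"
        )
    out: dict[str, dict[str, float]] = {}
    for name, sa in a.metrics.items():
        sb = b.metrics[name]
        out[name] = {
            "average_difference": abs(sa.average - sb.average),
            f"range_{a.label or 'a'}": sa.fluctuation,
            f"range_{b.label or 'b'}": sb.fluctuation,
            "range_difference": sa.fluctuation - sb.fluctuation,
        }
    return out
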