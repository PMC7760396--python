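"""Lumped (0D) compliant-chamber surrogate of the TCPC.

A single pressure chamber of compliance C (mL/mmHg) receives the two caval
inflows and drains through two linear outlet resistances to a common
downstream pressure:

    C dP/dt = Q_FP(t) + Q_SVC(t) - (P - P_out) (1/R_LPA + 1/R_RPA)

This is the minimal structure that supports the clinical compliance
estimate C = dV_max / dP_max (with V = C P + V_ref) and the rigid-versus-
compliant contrast: the time-averaged pressure drop and flow split are
independent of C in this linear model, while the pressure fluctuation
amplitude decreases monotonically with C (first-order low-pass,
|H| = R_par / sqrt(1 + (w R_par C)^2)).  It is a surrogate, not a
patient-derived model: downstream pressures and pulmonary resistances are
documented placeholders, and all assertions are C-relative.

The module also hosts the iterative stiffness calibration: a bracketing
root search on a monotone stiffness -> deformation-index forward model,
used to pick the wall-motion amplitude of the synthetic compliant series so
its deformation index matches a target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .mesh_and_fields import ScalarWaveform
from .synthetic_data import WallModelParams

__all__ = [
    "LumpedTCPCModel",
    "LumpedSolution",
    "simulate",
    "compare_rigid_compliant",
    "calibrate_stiffness",
    "wall_amplitude_from_stiffness",
]


@dataclass(frozen=True)
class LumpedTCPCModel:
    """Parameters of the single-chamber surrogate.

    Units are clinical: compliance mL/mmHg, resistances mmHg·s/mL, pressures
    mmHg, flows mL/s.  The default compliance 2.46 mL/mmHg is the
    patient-scale estimate for an intra-atrial TCPC; the outlet resistances
    (≈2 Wood units each side, here in mmHg·s/mL) and downstream pressure are
    placeholders of plausible pulmonary magnitude.
    """

    compliance: float = 2.46  # mL/mmHg; 0 -> rigid chamber
    r_lpa: float = 0.20  # mmHg·s/mL
    r_rpa: float = 0.20  # mmHg·s/mL
    p_out: float = 8.0  # mmHg
    q_fp: Callable[[np.ndarray], np.ndarray] = lambda t: np.full_like(
        np.asarray(t, dtype=float), 30.0
    )
    q_svc: Callable[[np.ndarray], np.ndarray] = lambda t: np.full_like(
        np.asarray(t, dtype=float), 15.0
    )
    p_init: float = 12.0  # mmHg
    v_ref: float = 60.0  # mL chamber volume at P = 0
    period: float = 0.86  # s

    def __post_init__(self) -> None:
        if self.compliance < 0:
            raise ValueError("compliance must be >= 0")
        if self.r_lpa <= 0 or self.r_rpa <= 0:
            raise ValueError("outlet resistances must be positive")

    @property
    def g_total(self) -> float:
        """Total outlet conductance 1/R_LPA + 1/R_RPA (mL/s/mmHg)."""
        return 1.0 / self.r_lpa + 1.0 / self.r_rpa

    @property
    def r_parallel(self) -> float:
        """Parallel outlet resistance (mmHg·s/mL)."""
        return 1.0 / self.g_total


@dataclass
class LumpedSolution:
    """Chamber pressure/volume and outlet flows over the simulated cycles."""

    pressure: ScalarWaveform  # mmHg
    volume: ScalarWaveform  # mL, V = C P + V_ref
    q_lpa: ScalarWaveform  # mL/s
    q_rpa: ScalarWaveform  # mL/s
    periodicity_residual: float  # |P(T_end) - P(T_end - T)| / max(range, eps)
    converged: bool
    model: LumpedTCPCModel

    def last_cycle(self) -> "LumpedSolution":
        """Restrict all waveforms to the final stored cycle."""
        t = self.pressure.times
        t0 = t[-1] - self.model.period
        sel = t >= t0 - 1e-12

        def cut(w: ScalarWaveform) -> ScalarWaveform:
            return ScalarWaveform(w.times[sel], w.values[sel], w.unit)

        return LumpedSolution(
            pressure=cut(self.pressure),
            volume=cut(self.volume),
            q_lpa=cut(self.q_lpa),
            q_rpa=cut(self.q_rpa),
            periodicity_residual=self.periodicity_residual,
            converged=self.converged,
            model=self.model,
        )


def simulate(
    model: LumpedTCPCModel,
    dt: float = 5.0e-4,
    n_cycles: int = 20,
    periodicity_tol: float = 1e-4,
) -> LumpedSolution:
    """Integrate the chamber ODE to a periodic steady state.

    Implicit Euler (exact per-step balance C (P_{k+1}-P_k)/dt =
    Q_in(t_{k+1}) - Q_out(P_{k+1})); the rigid case C=0 reduces to the
    algebraic balance P = P_out + Q_in R_parallel, satisfied exactly.
    Flags non-convergence of the cycle-to-cycle periodicity residual.
    """
    if dt > model.period / 100.0:
        raise ValueError("dt must be <= period/100 for a resolved cycle")
    n_per = int(round(model.period / dt))
    n = n_per * n_cycles
    t = np.arange(n + 1) * dt
    qin = np.asarray(model.q_fp(t), dtype=float) + np.asarray(model.q_svc(t), dtype=float)
    g = model.g_total
    p = np.empty(n + 1)
    if model.compliance == 0.0:
        p[:] = model.p_out + qin / g
    else:
        c = model.compliance
        p[0] = model.p_init
        denom = 1.0 + dt * g / c
        for k in range(n):
            p[k + 1] = (p[k] + (dt / c) * (qin[k + 1] + g * model.p_out)) / denom
    resid = abs(p[-1] - p[-1 - n_per]) / max(np.ptp(p[-n_per - 1 :]), 1e-12)
    converged = bool(resid <= periodicity_tol) or model.compliance == 0.0
    return LumpedSolution(
        pressure=ScalarWaveform(t, p, "mmHg"),
        volume=ScalarWaveform(t, model.compliance * p + model.v_ref, "mL"),
        q_lpa=ScalarWaveform(t, (p - model.p_out) / model.r_lpa, "mL/s"),
        q_rpa=ScalarWaveform(t, (p - model.p_out) / model.r_rpa, "mL/s"),
        periodicity_residual=float(resid),
        converged=converged,
    model=model,
    )


def compare_rigid_compliant(
    model: LumpedTCPCModel,
    dt: float = 5.0e-4,
    n_cycles: int = 20,
) -> dict[str, dict[str, float]]:
    """Run the configured compliance against C=0 with identical inflows.

    Reports, per condition, the fluctuation range and time average of the
    chamber-to-downstream pressure drop and the time-averaged outlet flow
    split; in the linear model the averages are C-independent while the
    compliant fluctuations are strictly smaller for any non-constant inflow.
    """
    sol_c = simulate(model, dt, n_cycles).last_cycle()
    sol_r = simulate(replace(model, compliance=0.0), dt, n_cycles).last_cycle()
    out = {}
    for label, sol in (("compliant", sol_c), ("rigid", sol_r)):
        dp = ScalarWaveform(
            sol.pressure.times, sol.pressure.values - sol.model.p_out, "mmHg"
        )
        q_l = sol.q_lpa.time_average()
        q_r = sol.q_rpa.time_average()
        out[label] = {
            "pressure_drop_avg_mmhg": dp.time_average(),
            "pressure_drop_range_mmhg": dp.vrange,
            "lpa_flow_fraction": q_l / (q_l + q_r),
            "q_lpa_avg_ml_s": q_l,
            "q_rpa_avg_ml_s": q_r,
        }
    out["difference"] = {
        k: abs(out["compliant"][k] - out["rigid"][k]) for k in out["rigid"]
    }
    return out


# ---------------------------------------------------------------------------
# Stiffness calibration
# ---------------------------------------------------------------------------


def wall_amplitude_from_stiffness(
    young_modulus_mpa: float,
    wall: WallModelParams = WallModelParams(),
    radius_cm: float = 1.09,
    pulse_pressure_mmhg: float = 0.8,
) -> float:
    """Map wall stiffness to the radial dilation amplitude of a thin-walled
    tube: eps = dP * R * (1 - nu^2) / (E * h).

    With the default stiffness (0.07 MPa), thickness (2 mm) and the
    patient-scale FP radius and cyclic pressure change, this gives an
    amplitude of order 1e-2, i.e. a deformation index of a few percent.
    """
    dp_pa = pulse_pressure_mmhg * 133.322
    e_pa = young_modulus_mpa * 1e6
    h_m = wall.thickness_mm * 1e-3
    r_m = radius_cm * 1e-2
    return dp_pa * r_m * (1.0 - wall.poisson_ratio**2) / (e_pa * h_m)


def calibrate_stiffness(
    target_di_percent: float,
    forward_model: Callable[[float], float],
    bounds: tuple[float, float],
    rtol: float = 1e-3,
    max_iter: int = 100,
) -> float:
    """Find the stiffness whose forward-model deformation index matches the
    target.

    ``forward_model`` maps a stiffness parameter to a deformation index (in
    percent) and must be monotone decreasing over ``bounds``; the root of
    DI(k) = target is bracketed and solved to relative tolerance ``rtol``.
    A target outside the attainable [DI(hi), DI(lo)] range is an error
    listing that range.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy lo < hi")
    di_lo = forward_model(lo)
    di_hi = forward_model(hi)
    if di_hi > di_lo:
        raise ValueError(
            "forward model is not decreasing over the bounds: "
            f"DI({lo:g})={di_lo:.3f}%, DI({hi:g})={di_hi:.3f}%"
        )
    if not (di_hi <= target_di_percent <= di_lo):
        raise ValueError(
            f"target DI {target_di_percent:.3f}% outside attainable range "
            f"[{di_hi:.3f}%, {di_lo:.3f}%] for stiffness in [{lo:g}, {hi:g}]"
        )
    if math.isclose(target_di_percent, di_lo, rel_tol=1e-12, abs_tol=1e-12):
        return lo
    if math.isclose(target_di_percent, di_hi, rel_tol=1e-12, abs_tol=1e-12):
        return hi
    return float(
        brentq(
            lambda k: forward_model(k) - target_di_percent,
            lo,
            hi,
            rtol=rtol,
            maxiter=max_iter,
        )
    )
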