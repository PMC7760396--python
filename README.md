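# tcpcflow

Hemodynamic post-processing for **total cavopulmonary connections (TCPC)** —
the surgical junction that routes both vena cavae directly into the
pulmonary arteries in single-ventricle (Fontan) palliation. Given a
time-resolved velocity/pressure solution on a tetrahedral mesh with labeled
vessel caps (Fontan pathway FP and superior vena cava SVC inlets, left/right
pulmonary artery LPA/RPA outlets), the package computes the metrics used to
judge a Fontan connection and to decide whether a rigid-wall simulation is
an adequate stand-in for a compliant one:

* **Wall-deformation metrics** — cross-sectional area waveforms `A(t)` and
  the deformation index
  `DI = (A_max − A_min) / A_mean × 100 %`;
  net flow `Q_net(t) = ΣQ_in − ΣQ_out`, the cavity volume
  `V(t) = V₀ + ∫ Q_net dt` (trapezoidal), and the compliance estimate
  `C = ΔV_max / ΔP_max` (mL/mmHg) with `P` the volume-averaged pressure.
* **Energy metrics** — FP→LPA pressure drop (area-averaged static pressure)
  and the control-volume power loss
  `PL = −Σ_caps ∫ (p + ½ρ|v|²)(v·n̂) dA`,
  with min/max/cycle-average summaries and rigid-vs-compliant differencing.
* **Lagrangian transport** — particles seeded at the FP cross-section and
  advected through the (periodically extended) flow with RK4; residence
  times, the 95 % washout time `W95`, and the hepatic flow distribution
  `%HFD(LPA) = 100 × N(FP→LPA) / N(FP→LPA or RPA)`, the fraction of
  hepatic-factor-carrying flow reaching the left lung.
* **A lumped compliant chamber** — a 0D surrogate
  `C dP/dt = Q_FP + Q_SVC − (P − P_out)(1/R_LPA + 1/R_RPA)` that isolates
  the effect of compliance: time averages are C-independent while
  fluctuation amplitudes shrink as `1/√(1+(ωRC)²)`; it also hosts the
  stiffness→deformation-index calibration loop.
* **A synthetic generator** — an idealized four-branch TCPC mesh and
  analytic rigid / prescribed-wall-motion field series with closed-form
  ground truth (exact cap fluxes, cubic-in-time cavity volume), so the whole
  pipeline is testable at desk scale without a CFD/FSI solver.

Fields are exchanged as per-frame legacy ASCII VTK (or `.vtu`) files plus a
YAML manifest; patch labels ride in a sidecar CSV.

## Worked example

```python
from tcpcflow import (SyntheticConfig, build_idealized_tcpc, make_field_series,
                      area_waveform, deformation_index, SeedingProtocol,
                      seed_particles, advect, residence_stats, hfd)

cfg = SyntheticConfig(edge_length_mm=2.5, frame_interval=0.02)
mesh = build_idealized_tcpc(cfg)
moving = make_field_series(mesh, cfg, "moving")   # compliant walls
rigid = make_field_series(mesh, cfg, "rigid")

p0, n = cfg.fp_probe_plane()
print(deformation_index(area_waveform(moving, p0, n, "FP")))

ens = advect(seed_particles(rigid, SeedingProtocol.desk_scale(seed=0)),
             rigid, substep=2e-3, horizon_cycles=5)
wash = residence_stats(ens, cycle_period=cfg.cycle_period)
print(wash.flag() or f"W95 = {wash.w95_s:.2f} s")
print(f"%HFD(LPA) = {hfd(ens).time_averaged_percent:.1f}%")
```

prints (2,244 nodes / 9,480 tetrahedra; 1,032 particles):

```
A_max=4.12 cm², A_min=3.91 cm², A_mean=4.01 cm², DI=5.2%
washout not reached (82.5%)
%HFD(LPA) = 50.3%
```

The deformation index of ~5 % reflects the configured wall-motion amplitude
(`wall_amplitude=0.013`, the scale of a compliant intra-atrial pathway); the
symmetric junction splits hepatic flow evenly (50.3 % to the LPA, a
statistical scatter of ±2 % at ~850 lung-bound particles); the washout flag
reports that 17 % of seeds — slow near-wall particles — outlast the 5-cycle
horizon, so `W95` is undefined and the achieved fraction is given instead.
Running the same protocol on the compliant series washes out faster, and the
rigid condition shows roughly twice the power-loss fluctuation range of the
compliant one with identical cycle averages — the central rigid-vs-compliant
contrast this package is built to quantify. (Instantaneous power loss of the
synthetic junction can be negative: the generator's fields are kinematic
stand-ins, not momentum solutions, so the energy flux bookkeeping is only
qualitative there; on the analytic pipe fixture `PL = ΔP·Q` holds to <1 %.)

A CLI mirrors the library: `tcpcflow synth | metrics | track | lumped |
compare | refine` (see `tcpcflow --help`).

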