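# Methods

This note records the models, numerical choices and known limitations of
tcpcflow, in the order the pipeline runs.

## Data model and units

All computation is in SI (m, s, Pa, kg); clinical units (cm², mL/s, mmHg,
mW) appear only at reporting boundaries, with 1 mmHg = 133.322 Pa applied
exactly there. Fields are nodal (P1): velocity and pressure are interpolated
linearly per tetrahedron and linearly in time between stored frames; the
stored cycle is extended periodically when a query time exceeds it. Physical
constants default to the standard resting Fontan assumptions: blood density
1000 kg/m³, kinematic viscosity 3.5×10⁻⁶ m²/s, cardiac cycle 0.86 s.

Boundary patches are facet-labeled (FP, SVC, LPA, RPA, WALL) with an
inlet/outlet registry. Mesh validation enforces positive cell volumes,
closure of the declared boundary against the actual unpaired tet faces, and
planarity of each cap.

## Geometric queries

* **Point location.** Barycentric containment with relative tolerance
  10⁻¹⁰. With a hint cell the locator walks through face neighbors (moving
  toward the most negative weight); otherwise, and as fallback, it scans the
  candidate cells of a uniform background grid in ascending index order, so
  ties on cell interfaces resolve deterministically to the lowest incident
  cell. For moving meshes the grid is inflated by the series' maximum nodal
  displacement. An exhaustive-scan locator is kept as the test oracle.
* **Boundary flux.** Exact integral of the P1 velocity's normal component
  per facet (area-weighted outward normal dotted with the vertex-mean
  velocity), signed positive into the domain at inlets and out at outlets.
* **Cross-sections.** Marching-tet plane cuts; per-cell intersection
  polygons (3–4 vertices, ordered azimuthally) summed over the single
  connected component of cut cells; multi-component cuts and empty cuts are
  errors. Areas are evaluated on the frame's (possibly deformed) positions.
* **Power loss.** Control-volume energy flux
  `PL = −Σ_caps ∫ (p + ½ρ|v|²)(v·n̂) dA`, integrated with the edge-midpoint
  rule (exact for the quadratic integrand on each facet). The signed
  instantaneous value may be negative under pulsatile flow. The
  energy-flux form (rather than volumetric viscous dissipation) is used
  because it is computable from boundary data alone and admits the negative
  instantaneous values observed clinically. Pressure drop uses area-averaged
  *static* cap pressure by default; a total-pressure variant is available
  via a flag.

## Synthetic TCPC generator

The generator emulates the statistical structure of a patient dataset —
pulsatile caval inflows of period 0.86 s, a compliant Fontan pathway, a
rigid companion with identical boundary conditions — with closed-form
ground truth. It is the test bed, not a flow solver.

**Geometry.** The junction is the union of a vertical circular duct (FP
below, radius 1.09 cm from the published mean FP area of 3.74 cm²; SVC
above, radius 0.80 cm from 1.99 cm²) and a horizontal duct (LPA/RPA,
0.65 cm, typical pulmonary calibre), voxelized on a Cartesian grid of the
configured edge length (default 1.5 mm, the "fine" resolution of the usual
mesh-sensitivity ladder) and split into six tetrahedra per hexahedron with
globally consistent face diagonals (diagonal through the smaller global
node index; the total order of each prism's base ids excludes the
untetrahedralizable cyclic case). Caps are exactly planar; the x/y cell
counts are forced odd so no node lies on the x=0 or y=0 symmetry planes.
The straight-pipe fixture is body-fitted instead (structured disk
triangulation extruded along the axis), because the analytic oracles —
cap area πR², flux Q, Hagen–Poiseuille ΔP = 8μLQ/(πR⁴), PL = ΔP·Q — must
converge smoothly under refinement; observed errors fall from ~14 % at
2 mm to <1 % at 0.5 mm, second order in edge length.

**Inflows.** Configurable truncated Fourier series around resting means
(FP 30 mL/s, SVC 15 mL/s ≈ 2.7 L/min total venous return, caval
pulsatility ~40 %/20 %). The published patient waveforms are not tabulated
anywhere, so no digitized values are used.

**Velocity field.** Each branch carries a parabolic (Poiseuille) profile of
its instantaneous flow along its axis, combined by a partition of unity
over the junction. Three field components exist purely so that Lagrangian
transport through the junction behaves like a junction flow:

1. *Outlet capture funnels.* Near the junction each PA field's support
   widens to span the whole duct-union cross-section and narrows linearly
   to the true PA radius at the end of the junction region, with the
   streamline-consistent radial component `v_ρ/v_x = (dr_eff/dx)·ρ/r_eff`;
   without the radial term particles stall on the funnel lip, and without
   the widening the duct-intersection corners are stagnation pockets.
2. *Caval swirl.* The FP inflow carries a solid-body secondary component
   (`fp_swirl_ratio = 0.3` of the local axial speed at the wall radius),
   tangential at the cap. Real caval inflow is not axisymmetric; here the
   swirl's role is to carry particles off the junction's knife-edge
   stagnation plane, which would otherwise trap the (measure-zero, but
   discretely sampled) particles that enter exactly on it.
3. *Discrete no-penetration.* The analytic profiles vanish on the ideal
   cylinder surfaces, not on the voxel mesh's staircase wall; the nodal
   velocity at wall nodes therefore has its wall-normal component (relative
   to the prescribed wall motion) removed. The projection is linear, so it
   commutes with the flux calibration below.

Each branch's nodal profile is rescaled once per mesh so that the discrete
facet quadrature at its cap carries exactly the prescribed flow. Inlet and
outlet flows are therefore consistent to machine precision — rigid-mode
mass closure is exact rather than mesh-limited. The interior blended field
is *not* divergence-free and not a momentum solution: energy fluxes through
the junction are only qualitatively meaningful (the pipe fixture carries
the quantitative energy oracles), and none of the analytic assertions are
made inside the blend region.

**Wall motion.** In moving mode the FP branch dilates radially,
`x' = x(1 + ε s(t) w(z))`, with `s = sin(2πt/T)`, amplitude ε
(`wall_amplitude`, default 0.013 — chosen to give a deformation index of
~5 %, the compliant intra-atrial scale) and a cos²-ramped plateau window
`w(z)` that vanishes at the FP cap and before the junction blend, so caps
and junction stay fixed. Because every node coordinate is linear in
`ε s w`, the exact mesh volume is a cubic polynomial in `s`; its
coefficients are obtained from four exact volume evaluations, giving a
closed-form `V(t)` and `dV/dt`. Outlet flows subtract this exact `dV/dt`
(split λ : 1−λ), so moving-mode mass balance at the caps is also exact,
and the net-flow waveform equals the analytic volume rate by construction.
The wall-motion velocity field `ε ṡ w(z) (x, y, 0)` is added everywhere in
the window so near-wall fluid follows the wall (particles cannot tunnel),
and the FP's local axial flow is reduced by the cumulative storage fraction
along the window. At a plateau cross-section the area scales exactly by
`(1 + ε s)²`, which is the oracle for the deformation-index tests
(`DI ≈ 4ε × 100 %` for small ε).

## Wall metrics

`A_mean` is the arithmetic mean of the area samples (matching the
"average area" usage of clinical tables, which assume uniform sampling);
DI is reported to one decimal. Volume integration uses the cumulative
trapezoid; the volume-averaged pressure weights each tetrahedron's
vertex-mean pressure by its (deformed) volume. Compliance is the ratio of
peak-to-peak volume to peak-to-peak volume-averaged pressure; applied to
the 0D chamber it recovers the configured C exactly since `V = CP + V_ref`.

## Particle transport

Seeding follows the study protocol: seeds at every interior node of the FP
cross-section (cap-rim nodes sit on the no-slip wall and are excluded),
inset 0.35 cell-lengths into the domain, one event per millisecond for one
cycle, tracked five further cycles — 700 × 860 ≈ 602,000 particles at full
scale. The desk-scale preset (20 ms events, 24 seeds/event ≈ 1,000
particles) runs in seconds-to-minutes; counts and intervals are free
parameters.

Advection is classical RK4 with a fixed substep (default 5×10⁻⁴ s, the
solver-scale step; tests use 1–2×10⁻³ s, under which exit times change by
<10⁻⁴ relative on the pipe fixture). Activation times snap to the substep
grid (exact when the seeding interval is a multiple of the substep).
Velocity lookups interpolate barycentrically in the cell found by a
vectorized neighbor-walk from each particle's previous cell; out-of-domain
RK4 stage points reuse the previous stage velocity. An endpoint that the
walk cannot place is either (a) an exit — the substep segment crosses a cap
plane inside the cap's facet set; the exit time is linearly interpolated —
or (b) a wall contact — the particle is returned to the last interior point
of the segment by batched bisection (a no-flux condition that conserves
particle count; the spec'd wall-normal projection is ill-defined on a
voxel wall's edges, and segment bisection is its robust equivalent).
Because the walk can misclassify interior points near non-convex staircase
notches, non-exit endpoints are re-checked against the grid locator (every
8th consecutive contact for persistent wall-grinders — a pure performance
measure; no particle can stay frozen by a stale verdict). Particles still
active at the horizon are marked stranded.

`W95` is the earliest absolute time (clock at t = 0, the start of seeding,
matching the usual cycles-conversion of washout tables) by which 95 % of
all seeds have exited; stranded particles count against it, and an
unreached washout is flagged with the achieved fraction rather than
extrapolated. Instantaneous %HFD bins lung-bound fates by seed time over
sliding windows (exit-time attribution is available), since the clinical
plot runs over one cardiac cycle of seeding; FP seeds that leave through a
caval cap (backflow) count as exited for washout but are excluded from the
HFD denominator, which is defined over lung-bound flow.

## Lumped chamber

Single pressure chamber, two linear outlet resistances, common downstream
pressure. Implicit Euler (dt ≤ T/100) satisfies the per-step balance
`C(P_{k+1}−P_k)/dt = Q_in(t_{k+1}) − Q_out(P_{k+1})` identically; C = 0
reduces to the exact algebraic rigid solution. At periodic steady state
(cycle-to-cycle residual ≤ 10⁻⁴, flagged otherwise) the linear model's
means are compliance-independent and its fluctuation amplitude follows the
first-order low-pass `|H| = R_∥/√(1+(ωR_∥C)²)` — the package's distilled
version of the rigid-vs-compliant contrast. Default parameters (C = 2.46
mL/mmHg; R = 0.20 mmHg·s/mL per lung; P_out = 8 mmHg) are plausible
magnitudes, not patient estimates; every assertion about the surrogate is
C-relative. Stiffness calibration maps Young's modulus to a dilation
amplitude via the thin-walled-tube relation `ε = ΔP·R(1−ν²)/(E·h)`
(defaults E = 0.07 MPa, ν = 0.3, h = 2 mm) and brackets the monotone
stiffness→DI forward model with `brentq` to 10⁻³ relative; replaying the
calibrated amplitude through the mesh cross-section pipeline recovers the
target DI within 0.2 percentage points.

## What the synthetic tests do and do not show

Passing tests demonstrate that the *metrics* are correct against closed
forms and that the *qualitative* compliance phenomenology (damped
fluctuations, unchanged averages, faster washout, preserved HFD) emerges
end-to-end. They do not validate any patient-specific value: the generator
has no anatomy, its junction field is kinematic, and its pressure field is
a resistive sketch. Quantities tied to a real flow solution — absolute
pressure-drop/power-loss extrema, washout seconds, residence-time modes —
are out of reach by design. At desk scale ~15–25 % of seeds are slow
near-wall particles that outlast the 5-cycle horizon (the same
boundary-layer dwell seen in rigid-wall clinical simulations), so TCPC
washout is typically reported as an achieved fraction; the rigid-vs-
compliant washout ordering is then asserted on that monotone equivalent.
For asymmetric outflow splits (λ ≠ 0.5) the blended junction sends
near-axis particles predominantly to the stronger outlet rather than
dividing them spatially as a momentum solution would; HFD claims are
therefore made only for the symmetric configuration, where the split is
50 % within binomial scatter.

## Problem sizes

Defaults were chosen so the full test suite completes in a few minutes:
TCPC meshes at 2.5–3 mm edge (4–10 k tets), 43–87 frames/cycle, ~1,000
particles over 5 cycles at 1–2 ms substeps; the analytic-oracle pipe at
0.5–1 mm (20–180 k tets, single frame). All are configuration parameters,
and the full-protocol preset remains available.
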