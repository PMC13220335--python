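# Methods

## Scope and model

`spongeflow` studies the passive hydrodynamics of the glass sponge
*Euplectella aspergillum* living alone or in pairs on the seafloor. The
flow around and through the tubular siliceous skeleton is solved with a
D3Q19 lattice Boltzmann method (LBM) in the single-relaxation-time (BGK)
approximation:

    f_i(x + c_i Δt, t + Δt) − f_i(x, t) = −(Δt/τ_f) [f_i − f_i^eq],

with the standard second-order truncated Maxwellian equilibrium

    f_i^eq = w_i ρ [1 + (c_i·u)/c_s² + (c_i·u)²/(2 c_s⁴) − u²/(2 c_s²)],

density ρ = Σ_i f_i, momentum ρu = Σ_i f_i c_i, and kinematic viscosity
ν = c_s²(τ_f − Δt/2) via Chapman–Enskog. All solver arithmetic is double
precision; collision conserves mass and momentum nodewise to machine
precision (asserted in the test suite on random states).

Five boundary conditions close the domain, matching the study setting of
a sponge standing on the seafloor in an oncoming current:

* **inlet** (upstream x plane): equilibrium populations at ρ=1 and the
  prescribed inlet velocity (equilibrium-inlet scheme — the simplest
  realization of a fixed-velocity inflow);
* **outlet** (downstream x plane): zero-gradient copy of density and
  velocity from the last interior plane, set as equilibrium populations;
* **periodic** side boundaries (y);
* **no-slip** halfway bounce-back on the bottom plane and at every
  solid–fluid link (second-order accurate; wall sits mid-link, and pairs
  exactly with the momentum-exchange force evaluation);
* **free-slip** specular reflection at the top plane.

The implementation is a fused stream-then-collide pass (numba) with a
bit-compatible pure-numpy reference path; the two are asserted identical
in the tests. An optional Guo-forced body force supports the
channel-flow validations.

### Validation

* Body-force-driven plane Poiseuille flow, 32 nodes across the gap:
  maximum deviation from the parabolic profile < 2% (measured ≈ 0.01%).
* Viscous decay of a sinusoidal shear mode matches exp(−νk²t) within 2%
  for τ_f ∈ [0.6, 1.5].
* Quiescent fluid exerts zero net force on any immersed solid (machine
  precision).
* A control-volume momentum + pressure budget around a plate in a duct
  balances the momentum-exchange drag within 3%.

## Digital-twin-lite geometry

The generator reproduces the skeleton's published architecture in
simplified, fully procedural form: a hollow cylindrical body cavity
(full scale H = 154 mm total height, D = 40 mm cavity inner diameter,
h = 100 mm cavity height) whose wall is a checkerboard lattice of
orthogonal struts (0.5 mm) reinforced by double diagonals (0.2 mm),
decorated by helical ridges (5 mm), capped by a perforated sieve plate
(osculum), and attached to the floor by a short solid base plug that
stands in for the anchoring bulb and the curved connecting section (the
analysis surfaces — cavity flow and drag — are dominated by the tube).
A voxel is solid iff its center lies inside the analytic solid
(unbiased volume, deterministic); members thinner than one voxel are
inflated to one voxel and the inflation is logged.

Parameters not published and fixed here as package defaults:

* **lattice pitch** (strut spacing): 5 mm at full scale, so the pores
  are an order of magnitude wider than the struts; the pore-to-viscous-
  length ratio drives the flow-admission physics, so this is a
  first-class configurable.
* **ridges**: 8, alternating handedness, one full turn over the cavity
  height. Half-slot phase offsets make a single sponge exactly
  mirror-symmetric about the plane through its axis, and hence a
  side-by-side pair mirror-symmetric about its mid-plane — the
  symmetry used to check left/right drag equality.

### Pair separation λ

λ is interpreted as axis-to-axis separation (`lambda_convention:
center`). The tightest published case λ=D is, however, unrealizable
under that convention: two wall shells around cavities of inner diameter
D must interpenetrate at an axis distance of D, and the ridged twin's
outer envelope exceeds D by a further 10 mm. A second convention
(`surface`) therefore maps λ=D to the outer envelopes just touching
(with one voxel of clear water), shifting λ by the constant envelope
excess so the sweep ratios {1, 3, 5} are preserved. Desk presets use
`surface`; the center convention remains the default for well-separated
pairs.

## Desk-scale study conditions

The production-scale study ran ~10¹¹-node grids; this package executes
the same algorithm at desk resolution. The desk preset keeps the full
morphology and Reynolds similarity but not strut-scale geometric
fidelity:

* cavity diameter D = 14 voxels (voxel size 2.86 mm at full scale);
* lattice pitch widened to 4 voxels so the wall pores stay open at this
  resolution; struts and diagonals inflate to one voxel;
* Re = 100 (plain BGK at coarse resolution is unstable and under-resolved
  at the production Re of 500–2000, which remain available behind an
  explicit `allow_under_resolved` flag);
* lattice inlet speed 0.07 (low-Mach), giving τ_f ≈ 0.529;
* 2600 steps (~1.5 domain transits), force averaging over the trailing
  half, force sampling every 10 steps;
* matched cross-run comparisons (isolated vs in-line vs side-by-side)
  share one explicit common domain — 113×71×71 for the λ=D trio — so
  blockage ratio, body position and outlet distance are identical.

Consequences: desk runs mirror the *signs and orderings* of the paired-
sponge effects (wake shielding, residence-time gains, side-by-side flow
enhancement), not the production-scale magnitudes. Absolute drag
coefficients, flow rates and residence times at this resolution are not
comparable to full-scale values.

## Forces

The force on a body is evaluated by momentum exchange over all
fluid–solid links, ΔP = Σ (f_i^in + f_ī^out) c_i Δx³ and F = ΔP/Δt;
with resting walls and halfway bounce-back, f_ī^out = f_i^in. Per-link
contributions are retained as wall-site tractions whose sum reproduces
the body total exactly. Drag is the force component along the incoming
flow, lift the horizontal transverse component (the vertical component
is excluded from lift by definition). Coefficients normalize by
½ρ|u_in|²A with A the voxel-counted projected silhouette of the body
perpendicular to the flow — reproducible for a porous lattice where a
bounding rectangle would overstate the obstructed section.

## Cavity pathlines and residence times

Pathlines are traced in the converged (statistically steady) velocity
field, where pathlines and streamlines coincide; unsteady tracking is
out of desk scope. Integration is fourth-order Runge–Kutta on a
trilinear interpolant, a quarter voxel per step, forward and backward
from each seed; seeds fill each cavity on a uniform grid with a
seed-controlled sub-voxel jitter (150 per cavity in the desk preset).
A line stops on leaving the domain or region, entering a solid voxel,
stalling below 10⁻⁶ of the inlet speed (stalled lines are flagged, not
dropped), or at the step cap.

Per line, length and residence time are the discrete sums

    l     = Σ_s ‖x(s) − x(s−1)‖,
    t_res = Σ_s ‖x(s) − x(s−1)‖ / (½‖u(s) + u(s−1)‖),

with zero-speed segments skipped under a warning. The residence time of
a cavity is accumulated over the *in-cavity* portion of each pathline
(the maximal in-mask run containing the seed): the quantity of interest
is the time a particle takes to enter and leave the cavity, and at desk
resolution requiring strict whole-line containment would retain almost
no lines in a well-flushed cavity. A strict whole-line containment
filter is also provided. Distributions ψ̃ are reported as raw samples
plus a Freedman–Diaconis histogram on log-scaled t_res, against the
ballistic cross time t_cross = D/|u_in|.

## Cavity flow rate

Each cavity's water admission is measured through the cylinder inscribed
in the body cavity, partitioned into six oriented surfaces: the two
bases (cavity floor and the disc under the osculum) and four equal
lateral quarter-panels. Fluxes are midpoint quadratures of u·n dA with
trilinearly interpolated velocity at half-voxel resolution; the lateral
radius is shrunk by one voxel of wall clearance so the quadrature stays
clear of strut intrusions (the largest cylinder truly inscribed in the
fluid). The net six-surface flux is ~0 by incompressibility (closure
checked, ≈1% in converged desk runs); the *inflow* is the sum of inward
contributions only — the only reading under which admission is nonzero —
converted to litres per hour through the unit scaling.

## Units

Lattice runs are dimensionless (Δx = Δt = 1, outlet density ρ_out = 1).
Dynamic similitude is enforced by matching Re = |u_in|D/ν; the scale
factors are δx (m per lattice spacing), δν (m²/s per lattice viscosity),
the derived δt = δx²/δν, and a mass scale from the physical seawater
density (default 1025 kg/m³; the working viscosity is 1.75×10⁻⁶ m²/s).
Forces scale as (ρ_phys/ρ_out)·δx⁴/δt². The physical regime fixes
only the physical side; the lattice inlet speed is a free stability
choice (≤ 0.1) from which the lattice viscosity and τ_f follow. Round
trips and Re invariance are property-tested to 1e-12.

## Numerical choices and degenerate inputs

* τ_f ≤ Δt/2 (non-positive viscosity), |u_in| > 0.1, zero dynamic
  pressure, empty masks/solids and unknown body labels are rejected with
  field-level errors; population blow-up raises a stability error naming
  the step and suggesting remedies.
* Convergence: windowed relative change of total kinetic energy and of
  summed drag both below 1e-4 over the configured window, or the step
  cap. Max |u| above 0.15 lattice units raises a low-Mach warning.
* STL export is a marching-cubes isosurface (watertight, padded);
  voxelization back is a vertical ray-parity fill per voxel-center
  column, written in-package because no installed dependency provides
  point-in-mesh containment.

## Known limitations

* Desk resolution: one-voxel struts make the wall's local porosity
  resolution-limited; pore-scale boundary layers are not resolved.
* The skeleton is rigid and bare: no soft tissue, no active pumping, no
  flexural response to the computed loads.
* BGK without a subgrid model restricts desk runs to Re ≲ 300.
* Pathline counts depend on seeding density and termination rules, so
  only distributional shape — not absolute counts — is meaningful.
* The osculum sieve and base plug are stylized; only their blocking role
  is represented.
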