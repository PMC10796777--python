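# Methods

`laflow` simulates blood flow in a moving, idealized left atrium (LA) with
four pulmonary-vein (PV) inlets and a mitral-valve (MV) outlet, performs
virtual single-vein resections, and quantifies the resulting flow with
pathlines, backward finite-time Lyapunov exponents (FTLE), kinetic energy
and viscous dissipation rate. This note records the model, the numerical
choices, and what the synthetic setting does and does not represent.

## Synthetic anatomy and wall motion

The chamber is an ellipsoid (default semi-axes 32 x 27 x 26 mm) meshed as a
subdivided icosphere; straight cylindrical tubes are stitched onto it for
the four PVs and the MV, with a funnel blend at each attachment. Port caps
are exactly planar regular polygons whose radius is corrected so the cap
area equals the configured cross-sectional area. Four subject presets carry
the cardiac period and the four PV areas of the study population the
package emulates; the key contrast is between *left-dominant* subjects
(LSPV among the largest veins, subjects 1-3) and a *right-dominant* subject
(LSPV the smallest vein, subject 4).

Attachment directions are fixed design choices that reproduce the textbook
asymmetric inflow arrangement: the left veins aim across the chamber toward
the right/anterior wall, the right veins aim into the inferior LA, and the
mitral orifice faces antero-inferiorly. They were chosen from anatomy (with
a pairwise tube-clearance check), not fitted to any output.

Wall motion is volume-driven: at each of 20 phases the chamber is scaled
uniformly about its centroid so the enclosed mesh volume matches a
prescribed periodic LA volume curve; tubes translate rigidly with their
attachment points. The per-phase scale factors are interpolated in time by
a Fourier series (order K = 9 over 20 phases). Because every vertex
position is affine in the scale factor, the per-vertex Fourier model is
obtained exactly by composition, and the same scale series drives an
*analytic twin* of the mesh (ellipsoid + capped cylinders) whose signed
distance and wall velocity the solver evaluates every step. Mesh and twin
are mathematically consistent by construction; the mesh-based signed
distance path (`surface_to_sdf`, brute-force point-triangle distance with
a generalized-winding-number sign) exists for user-supplied surfaces and is
cross-checked against the twin in the tests.

Default volume curves (Fourier fits of sketched keyframes): the LA curve
rises through ventricular systole to a late-systolic maximum near 0.4 T,
empties during early diastole, plateaus at diastasis and empties again with
the atrial kick; the LV curve ejects over 0-0.35 T and fills in an E-wave /
diastasis / A-wave pattern. Only the LV curve's positive rate is used (it
prescribes the MV flow). The LA level is the *total enclosed* volume
including the artificial extension tubes, hence higher than an imaging LA
volume. Default extension-tube lengths are three diameters for PVs (to push
the artificial pressure boundary away from the chamber) and 1.2 diameters
for the MV, which only hosts the prescribed-velocity outlet plane.

Virtual resection truncates one PV at a configurable stump depth (default
5 mm) and closes it with a quarter-ellipse bulged cap of height 10 % of the
tube radius; the profile meets the cylinder wall tangentially, so the
maximum dihedral angle across the cap stays well below 60 degrees. The
resected case reuses the pre-resection scale series: chamber motion, all
other ports, and the volumetric forcing are bitwise-unchanged between the
five cases of one subject.

## Flow solver

Incompressible Navier-Stokes with blood parameters rho = 1050 kg/m^3,
eta = 3.5 mPa s, on a uniform staggered (MAC) Cartesian grid, advanced by a
fractional-step scheme:

1. provisional velocity: Adams-Bashforth-2 convection with upwind-biased
   third-order (QUICK) face interpolation, explicit Euler diffusion;
2. immersed-wall treatment (below);
3. variable-coefficient pressure Poisson equation, Dirichlet pressures on
   the PV port layers, Neumann elsewhere;
4. projection.

QUICK rather than pure centered convection: at the coarse grids this
package targets, the cell Peclet number is O(10^2) and a centered convective
term accumulates grid-scale oscillations; QUICK's scale-selective
dissipation is negligible on resolved scales, which the decaying-vortex
benchmark quantifies (amplitude error ~0.1 % over an e-fold at 64^2).

The time step obeys CFL <= 0.1 with respect to the current maximum speed
and the anticipated valve-opening speed, an explicit-diffusion bound
h^2/(6 nu), and an absolute cap of T/600.

### Immersed wall

A boundary-data-immersion weight mu in [0, 1] is evaluated from the signed
distance with the smooth kernel mu(d) = 1/2 (1 - d/eps - sin(pi d/eps)/pi)
over a band of half-width eps = 2h. The weights enter the projection as
face coefficients, restricted to faces between two fluid cells — without
this restriction the large port/chamber pressure differences pump a
spurious circulation through the permeable diffuse wall.

Momentum faces excluded from the projection are prescribed in three
classes:

- **mass faces** (boundary of the fluid region): frozen at (1 - mu) w,
  where w is the wall velocity. The volume rate this discretely realizes
  differs from the analytic chamber rate by O(h/R) (a single crossing face
  per normal line carries only ~(1 - mu) ~ 1/2 of the wall speed), so a
  per-step global factor lambda ~ 2 rescales the motion field to make the
  discrete wall source equal d(V_chamber)/dt exactly; the MV piston speed
  is likewise set to Q_MV divided by the *discrete* piston footprint.
  After this calibration the per-step port bookkeeping closes to solver
  tolerance.
- **ghost faces** (solid-side faces within the band, which appear only in
  viscous/advective stencils): mirrored values 2 w - u(mirror) across the
  interface, a sharp second-order no-slip. The plane-channel benchmark
  (16 cells across the gap) gives a 0.3 % L2 profile error; the
  first-order blended alternative displaces the effective wall by O(eps)
  and misses the profile by ~20 %.
- deep solid faces: the wall velocity itself (zero away from the band).

Fluid-side faces are never damped toward the wall.

### Boundary ports

Each PV carries a resistance-type pressure boundary P = P0 + K_i Q with
P0 = 0 and K_i = kappa / A_i (kappa = 5 Pa s/mm), applied as a Dirichlet
pressure on a two-cell layer near the tube end, with Q the flux *toward the
vein* so that inflow pulls the boundary pressure below baseline (the
stabilizing direction; with the opposite sign convention the coupling is a
positive feedback). The coupling is lagged by one step. Inverse-area
resistances encode the equal-design-velocity assumption across veins; in
the runs the cycle-mean inflow speeds of the four veins indeed agree to a
few percent. Port fluxes are recorded as the exact discrete flux through
each port's boundary layer (cell volume times divergence, by Gauss), which
is what the mass-balance checks audit; a disk-quadrature plane flux is
available as `port_flux`.

The MV is a wall while the ventricle ejects (dV_LV/dt < 0) and a
uniform-velocity outlet while it fills, with a 1 ms hysteresis on the sign
changes. The outlet is realized as a piston band at the MV tube end whose
prescribed speed delivers exactly the valve flow rate.

### Pressure solve

The Poisson system is solved by conjugate gradients preconditioned by a
geometric multigrid V-cycle (coefficient averaging, block-OR masks,
symmetric forward/backward Gauss-Seidel smoothing), typically 8-13
iterations per step with warm starts extrapolated from the two previous
pressures. Stopping requires both the maximum divergence residual (target
4e-7 U/h, comfortably inside the 1e-6 U/h bound asserted by the tests) and
the residual *sum* (which would otherwise surface as spurious created mass
in the port bookkeeping). When no Dirichlet port is active (benchmark
boxes) the singular Neumann system is gauge-fixed by mean subtraction.

## Postprocessing

Velocity snapshots are stored every 10 ms over the final cycle (float32).
Tracers use classical RK4 on velocities interpolated trilinearly per
staggered component and linearly in time; tracers crossing into the solid
are frozen. Pathlines are seeded on the active PV port disks every 10 ms
from 0 T to 0.35 T of the analysis cycle (seed-jittered; the only use of
the random seed). Backward FTLE (tau = -50 ms) is computed on the
horizontal plane through the mean of the PV port centers, seed spacing
h/2; the exponent is ln(sigma_max)/|tau| with sigma_max the largest
singular value of the in-plane flow-map gradient (equivalently half the
log of the largest Cauchy-Green eigenvalue — the standard convention;
where the norm convention of a reported FTLE is ambiguous this is the one
implemented). Seeds whose finite-difference neighbors left the fluid are
flagged, not extrapolated.

Kinetic energy and dissipation rate are cell sums of (1/2) rho |v|^2 and
2 eta S:S. Cells inside the BDIM band are weighted by their fluid fraction,
since the diffuse wall otherwise contributes O(U/eps)^2 spurious shear —
this near-wall treatment is the dominant systematic between
implementations of the dissipation integral. The analysis domain is the
chamber plus any resected stump, excluding the artificial extension tubes
(configurable).

## Problem sizes and scaled-down experiment

The package's own test and reproduction runs use deliberately small
problems: the five-case experiment (pre-resection + four single-vein
resections) runs per subject on a 28^3 grid (h ~ 5-6 mm, about 11 cells
across the chamber) for two cardiac cycles, analyzing the second; the
mass-balance audit runs one cycle at 40^3; benchmarks use 64^2 (vortex) and
a 16-cell channel gap. Full-resolution grids (e.g. 256^3 at 0.6 mm) are
supported by the configuration but are not exercised by the tests. At the
experiment scale the energetics are qualitative: rankings and fold-changes
between cases of one subject are meaningful, magnitudes are
resolution-dependent (peak kinetic energies come out at a few mJ, the same
order as physiological reports; dissipation rates are damped by the coarse
grid).

## What the synthetic data does not show

The generator emulates the *structure* of the study inputs — four-vein
moving anatomies with subject-specific vein calibers and period, reciprocal
LA/LV volume exchange, cylindrical boundary extensions — not real atria:
there is no appendage, no patient-specific wall shape or regional motion,
vein angulation is idealized, and the volume curves are sketched, not
measured. Passing tests therefore demonstrate solver and pipeline
correctness and the robustness of *relative* statements (flux
redistribution after resection, dissipation rankings between resections,
left- vs right-dominant contrast), not patient-level prediction.

## Known limitations

- The lagged (explicit) resistance coupling is stable here because the
  port inertial time constant is milliseconds, but a very large kappa with
  a very large time step could require sub-iteration.
- The wall-flux calibration factor lambda is a single global scalar; it
  enforces the global volume rate, not the local distribution of the wall
  source, whose error remains O(h/R).
- Dissipation near the immersed wall is under-counted by the fluid-fraction
  weighting (deliberately, to avoid the much larger spurious-shear bias).
- The MV piston prescribes a flat outflow profile; no valve leaflets.
- At 28^3, the smallest veins are 2-3 cells across; their jets are
  represented but not resolved.
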