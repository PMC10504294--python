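# Methods

`nanotear` models how flowing water kills bacteria on a carbon-coated
nanowire (nanotip) surface: cells carried by mild laminar flow collide with
sharp vertical tips, are held there transiently by London dispersion
adhesion, and the drag of the continuing flow tears the cell envelope. The
package implements the full desk-scale analysis chain — flow, transport,
contact statistics, contact mechanics, and disinfection bookkeeping — with
synthetic-data generators so that every stage is testable without any
external dataset. This note records the models, their assumptions, the
parameter choices, and the known limits of each stage.

## 1. Stokes flow (`flow_field`)

**Model.** Steady incompressible creeping flow,
`-mu lap(u) + grad p = F`, `div u = 0`. At the operating conditions the
Reynolds numbers are tiny — `Re ~ 1e-4` at a 200-nm tip in a 5.5e-4 m/s
stream, `Re ~ 0.2` for 1 mm/s through 200-um foam pores — so dropping the
inertial terms is faithful; the solver records a warning whenever a
configuration leaves `Re <= 1`.

**Discretization.** Uniform staggered (MAC) grid; velocities on cell faces,
pressure at centres. Solids enter as a binary cell mask: every face touching
a solid cell is eliminated with zero velocity, a first-order "staircase"
no-slip. Boundary conditions per box face: `inlet` (Dirichlet velocity),
`wall`, `outflow` (zero normal gradient, ambient pressure), `symmetry`
(free slip). For the tip array the 45-degree incident flow is decomposed
onto the box: the top and upstream faces are inlets carrying
`U (cos 45, 0, -sin 45)`, the downstream face is the outflow, the base is a
wall — a box-grid rendering of a triangular domain whose hypotenuse is the
inlet. Fluid pockets disconnected from the open boundaries are closed off
before solving (their pressure is undefined).

**Solver.** The symmetric saddle system `[[A, G], [G^T, 0]]` is
nondimensionalized (lengths by the cell width, velocities by the inlet
scale) and solved by MINRES with a block-diagonal preconditioner: each
velocity block by a DST/DCT diagonalization of its unmasked Laplacian
(exact away from obstacles), the pressure block by the identity (the Stokes
Schur complement is spectrally equivalent to the pressure mass matrix).
MINRES runs in restart chunks against the physical convergence criterion —
the maximum cell divergence normalised by `inlet_speed / spacing` must fall
below `tolerance` (default 1e-6); exhausting the iteration budget raises an
error carrying the residual history.

**Verification.** A body-force-driven plane channel reproduces the
parabolic Poiseuille profile to <0.1% at 32 cells across the gap and the
error falls monotonically under refinement; a uniform inlet in an empty box
is reproduced to machine precision; fields scale linearly with inlet speed
(Stokes linearity); global influx/outflux balance to <1e-3 and plane-wise
flux in channel-like solves is constant to <1e-3.

**Problem sizes.** The bench tip-array solve (5x5 tips, d = 200 nm,
L = 5 um, 1-um gaps) uses 50-nm spacing — four cells across a tip diameter,
a (124, 124, 120) grid — and converges in a few hundred MINRES iterations.
Foam solves use `mean_pore / 20` spacing by default. The near-wall speed
reported by the pipeline is measured one grid cell from the nearest solid
face; on the bench array it is of order 1e-4 m/s with a floor of ~5e-6 m/s
at the closest resolved cells, bracketing the ~5e-5 m/s scale that the
downstream mechanics stage adopts as its near-surface speed. This quantity
is resolution-dependent and is treated as an order of magnitude only.

## 2. Foam transport (`foam_transport`)

A bacterium is a 1-um sphere at water density. Its velocity response time
`tau_p = m / (3 pi mu d) ~ 6e-8 s` is far below any useful time step, so the
default integrator is the overdamped Langevin update
`dr = u dt + sqrt(2 D dt) xi` with the Stokes-Einstein diffusivity
`D = k_B T / (6 pi mu r) = 4.4e-13 m^2/s` at 298 K (the temperature is a
package default; 298 K is ordinary lab water). An inertial integrator — the
exact Ornstein-Uhlenbeck discretization, valid for any `dt / tau_p` — exists
for verification and agrees with the overdamped limit on capture statistics
within Monte-Carlo error. Gravity is omitted (negligible for micron
particles in water). Particles release uniformly over the fluid inlet face,
stick permanently at first wall contact (centre within one radius of the
solid, evaluated on the analytic sphere model of the foam rather than the
raster), escape across the outlet, and reflect at the lateral symmetry
boundaries. A guard rejects time steps whose worst-case displacement
(max speed times dt plus three noise standard deviations) exceeds one grid
cell, which would allow wall tunnelling.

The >99.9999% capture claim for a 3-mm foam is an extrapolation, not a
direct simulation: the simulated slab is ~0.5 mm, and
`extrapolate_collision_probability` applies an independent-layer model
`P = 1 - escape^ratio`. Real layers are correlated through the flow; the
operator is exact arithmetic on an idealisation, and the tested property is
the monotone rise of capture with thickness, not the printed probability.

## 3. Bead-stick contact simulation (`nanotip_contact`)

**Cell model.** Two beads of diameter 0.5 um joined by a stiff harmonic
spring with rest length 0.5 um — a 0.5 x 1 um rod, matching the
spherocylinder used by the mechanics stage. Per-bead friction is the Stokes
value `xi = 6 pi mu a` (bead-bead hydrodynamic interaction neglected).
Each bead follows the overdamped Langevin equation with the local flow
velocity, Brownian noise, the spring force, and a short-range harmonic
repulsion (10-nm range) from tips and base plane. Spring stiffness
2e-4 N/m keeps the thermal bond-length RMS at 0.9% of rest length
(`sqrt(k_B T / k)`); the default `dt = 1e-6 s` is 2.4x inside the stability
bound `xi / (10 k)` and is validated at call time.

**Release and termination.** Cells start with isotropic random orientation
on a plane midway between the tip tops and the domain ceiling, spanning the
array footprint shifted upstream so a ballistic 45-degree descent lands on
the array. A run ends at first tip contact (surface gap <= 5 nm), at the
base substrate, on leaving the domain, or at `max_time` (default 0.05 s,
chosen so that in the bench geometry no cell times out — every cell either
contacts or exits).

**Contact classification.** The closest approach between the cell's
spherocylindrical surface and each tip (a capped cylinder) is minimised
along the cell axis by golden-section search (the distance to a convex
solid is convex along a segment). A contact is **end** when the minimiser
sits at a bead centre — the tip touches a polar cap — and **middle** when
it is interior (lateral side). At the bench geometry cap and side surface
areas are exactly equal, so the classification carries no a-priori bias.
An eight-way subtype code (leading/trailing bead x tip top/side/rim for end
contacts; apex/shaft for middle) is a declared reconstruction; only the
end/middle dichotomy is used quantitatively. With increasing cell aspect
ratio the lateral surface grows while the caps do not, and the end fraction
correspondingly falls; it exceeds the middle fraction for the moderate
aspect ratios (~2-2.5) that include the bench cell.

**Result.** In the solved bench field, pooled batches give an end-contact
fraction of 0.59 +/- 0.02 (six independent 100-cell batches spanning
0.54-0.64), statistically consistent with the 57%/43% end/middle split the
analysis targets.

## 4. Cell mechanics (`cell_mechanics`)

**Indentation and fitting.** Sneddon cone
(`F = (2/pi) tan(alpha) E* delta^2`) and Hertz sphere
(`F = (4/3) E* sqrt(R) delta^{3/2}`), with `E* = E / (1 - nu^2)` and
`nu = 0.5` (incompressible cell) by default. `fit_modulus` does linear
least squares in the prefactor over an early-indentation window (default:
the first half of the indentation range); recovery is exact at zero noise
and the median error stays below 10% at 5% force noise. `detect_puncture`
returns the displacement of the last force peak before the first drop
exceeding a threshold fraction of the running maximum.

**Rupture stresses.** Both loading modes use one closed-form family — the
concentrated-load bending stress of a thin plate/shallow shell (Roark):

    sigma = 3 P / (2 pi t^2) * [(1 + nu) ln(b / a') + 1],

with `b` the supported patch radius and `a'` Roark's equivalent contact
radius, which regularises loads concentrated below the thickness scale.

*Collision*: the impact energy (cell kinetic energy at the near-surface
speed, `E_k = 2e-25 J` for the 0.5 x 1 um spherocylinder at 5e-5 m/s) is
stored in the Reissner point-load stiffness of the envelope,
`k = 4 E t^2 / (R sqrt(3 (1 - nu^2)))`, giving a peak transmitted load
`P = sqrt(2 E_k k)`; the stress is evaluated in the composite envelope
(default t = 20 nm, the Gram-negative envelope scale) with the contact
radius from the Hertzian estimate at the contact curvature (cell cap on the
flat tip top for end contact; crossed cell-side/tip-rim curvatures for
middle). At the bench inputs this gives ~1.6e-4 MPa — two orders below the
0.05 MPa critical stress.

*Tearing*: the Stokes drag on the anchored cell
(`F_D = 3 pi mu d du = 4.7e-13 N` at d = 1 um, du = 5e-5 m/s) is
transmitted through the adhesive contact as a point load on the
load-bearing outer membrane (default t = 4 nm, a lipid bilayer — the layer
that observably ruptures, with 100-200-nm membrane fragments left on the
tips), over a patch set by the tip radius. This gives ~0.11 MPa, above the
critical stress, and the stress is linear in drag.

The choice of load-bearing thickness is the decisive modelling commitment:
a blunt compression engages the whole envelope, while peel loading at a
molecular adhesion line concentrates in the outer bilayer. Both thicknesses
are standard Gram-negative values and are configurable. The finite-element
stress magnitudes this replaces are mesh- and model-dependent; only the
ordering (collision << critical <= tearing, a >=2-order gap) and orders of
magnitude are asserted anywhere.

**Critical stress.** `sigma_c = 0.05 MPa` is taken as an input constant —
the puncture threshold obtained by AFM — rather than re-derived. The
verdict rule is inclusive: `ruptured` iff `max_stress >= sigma_c`.

## 5. Disinfection metrics (`disinfection_metrics`)

Plate-count concentration is the mean over countable plates (30-300
colonies, the standard spread-plate window; configurable) of
`count x dilution / plated_volume`, with 0.1 mL as the default plated
volume (standard spread-plate practice). A sample with zero colonies on
every plate is below the 1 CFU/mL detection limit and log removal credits
`log10(C0)` (complete inactivation); otherwise removal is `-log10(C/C0)`.
Residence time uses the bulk foam volume without porosity correction —
`78.5 mm^2 x 4 mm / 2.7 mL/min = 7.0 s` — which is the convention that
makes the flux (2.06 m^3 h^-1 m^-2), contact time, and treated volume
(116.64 L over 30 days; capacity ratio 10,701 with V_0 = 10.9 mL) mutually
consistent. The printed `V_0 = 10.9 mL` is taken as an input rather than
re-derived from chamber dimensions.

## 6. Synthetic data (`synthetic_data`)

*Foam*: an inverse-opal Boolean model — spherical voids with diameters
~N(mean_pore, 10%) carved from a solid slab until a raster measure reaches
the target porosity (a final oversized void is shrunk rather than allowed
to overshoot the solid-fraction band). This reproduces an open-cell
topology with one parameter; it does not reproduce the ligament-strut
texture of a real metal foam, so absolute capture efficiencies are
generator-dependent even though the monotone trends (thickness, porosity)
are not. *Tip array*: deterministic geometry. *Force curves*: the forward
contact model on an even grid, an optional constant force drop beyond the
puncture depth (default 30% of the breakthrough force), Gaussian noise.
*Plate counts*: Poisson draws with mean `conc x volume / dilution`. Every
generator consumes a single integer seed through one `numpy` generator, so
fixed seeds give identical outputs.

Passing tests on these generators demonstrates correctness of the
algorithms under the stated models — not agreement with any particular
physical foam or AFM instrument.

## 7. Numerical choices and degenerate inputs

- Divergence tolerance 1e-6 (of inlet speed per cell width) by default;
  heavy test fixtures use 1e-5 where no asserted statistic needs more.
- Golden-section contact search: 28 iterations (bracket ~1e-6 of the cell
  length); endpoint minima are detected explicitly so cap contacts are not
  mistaken for side contacts.
- Tie rules: rupture verdict inclusive at the critical stress; puncture
  detection at threshold zero degenerates to the first non-increasing
  sample.
- Degenerate inputs rejected with messages: non-positive domain extents,
  porosity outside (0, 1], overlapping tips (gap <= 0), negative noise SD,
  unstable time steps, out-of-domain sampling positions.
- `porosity = 1` is an explicit empty-foam case: no solid, infinite
  clearance, nothing to collide with.

## 8. Known limitations

- Staircase no-slip is first-order; near-wall speeds are order-of-magnitude.
- The bead-stick model omits bead-bead and bead-wall hydrodynamic
  interactions (lubrication), cell motility, and adhesion-bond kinetics;
  contact statistics reflect geometry and Brownian transport only.
- The eight-subtype taxonomy is a reconstruction; alternative subtype
  definitions would redistribute counts within (not between) the end and
  middle classes only if they respect the cap/side boundary.
- The rupture-stress models are single-layer closed forms; turgor pressure,
  the peptidoglycan network, and viscoelasticity are out of scope.
- The 3-mm capture probability is an independent-layer extrapolation from
  a ~0.5-mm simulated slab.
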