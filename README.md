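# nanotear

Mechanistic analysis of flow-driven bacterial inactivation on nanotip
surfaces — a copper-foam filter whose surface is covered with sharp,
carbon-coated nanowires. Bacteria carried by mild laminar flow collide
with the tips, are held by London dispersion adhesion, and the drag of the
continuing flow tears the cell envelope open. `nanotear` implements the
complete desk-scale modelling chain that supports this mechanism, for
researchers in microbial biophysics and water disinfection who want to
reproduce, probe or extend the analysis:

1. **Stokes flow** around the porous foam and around a 5x5 array of
   vertical nanotips (d = 200 nm, L = 5 um, 1-um gaps) on a staggered
   grid, solved as a symmetric saddle system with MINRES.
2. **Brownian transport** of 1-um spherical bacteria through the foam
   (overdamped Langevin, `dr = u dt + sqrt(2 D dt) xi`), with
   stick-on-contact walls and capture statistics.
3. **Bead-stick contact simulation**: a rod bacterium as two 0.5-um beads
   on a stiff spring, advanced by
   `dr_i/dt = V(r_i) + (F_B + F_S + F_wall)/xi`, with first tip contacts
   classified as **end** (polar cap) or **middle** (lateral side).
4. **Cell mechanics**: Sneddon/Hertz force-curve fitting
   (`F = (2/pi) tan(alpha) E/(1-nu^2) delta^2`, Young's modulus
   E ~ 0.5 MPa), puncture detection, and the collision-versus-tearing
   stress assessment against the critical envelope stress
   sigma_c = 0.05 MPa.
5. **Disinfection metrics**: CFU plate counts, log removal
   `-log10(C/C0)`, flux, residence time, treating capacity.
6. **Synthetic data generators** (foam geometry, tip arrays, AFM curves,
   plate counts) so that every stage runs and is tested without any
   external dataset.

## Worked example

Assess whether a collision or flow-driven tearing can rupture an *E. coli*
cell at the bench operating point (near-surface flow 5e-5 m/s, modulus
0.5 MPa, 200-nm tip):

```python
from nanotear import cell_mechanics as cm

e_k = cm.kinetic_energy(0.5e-6, 1.0e-6, 1000.0, 5e-5)   # 2.05e-25 J
drag = cm.stokes_drag_force(1e-6, 1e-3, 5e-5)           # 4.71e-13 N

collision = cm.collision_stress(e_k, 0.5e6, contact_form="end")
tearing = cm.tearing_stress(drag, contact_form="end")
print(f"collision: {collision.max_stress:.3g} Pa -> {collision.verdict}")
print(f"tearing:   {tearing.max_stress:.3g} Pa -> {tearing.verdict}")
```

prints

```
collision: 160 Pa -> intact
tearing:   1.06e+05 Pa -> ruptured
```

A collision stores its kinetic energy in the thin-shell stiffness of the
envelope and produces ~1.6e-4 MPa — two orders of magnitude below the
0.05 MPa rupture threshold, so impacts alone leave cells intact. The same
Stokes drag applied through the adhesive contact onto the 4-nm outer
membrane concentrates to ~0.11 MPa, above threshold: tearing, not
collision, ruptures the cell. The hydraulic bookkeeping at the same
operating point (2.7 mL/min through 78.5 mm^2 of 4-mm foam) gives a 7.0-s
contact time, a flux of 2.06 m^3/h/m^2, and 116.64 L treated in a 30-day
run — over 10,000 chamber volumes.

The stochastic half of the story — how often a rod-shaped cell first
touches a tip with its end versus its side — comes from the solved
tip-array flow plus the bead-stick simulation:

```python
from nanotear import (FluidProperties, generate_tip_array, solve_flow,
                      simulate_contacts, contact_statistics)

tips = generate_tip_array()                      # 5x5, 200 nm, 5 um, 45 deg
field = solve_flow(tips, FluidProperties(), inlet_speed=5.5e-4)  # ~5 min
events = simulate_contacts(field, tips, n_cells=100, seed=0)
print(contact_statistics(events))
```

Pooled over batches this yields an end-contact fraction near 0.6
(individual 100-cell batches span 0.54-0.64) — rod ends reach the tips
more often than the rod side does, which is why the end-contact stress
geometry dominates the rupture pathway.

A `nanotear` command groups the same stages as subcommands
(`flow solve`, `foam track`, `tips simulate`, `afm fit`, `stress assess`,
`stats removal`, `stats capacity`, `pipeline run`), each a thin wrapper
over the library; `pipeline run` chains them into one reproducible report.

## Documentation

`docs/methods.md` describes the models, assumptions, parameter defaults
and limitations of every stage.
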