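# perfuse

Quantitative toolkit for **microfluidic perfusion cell culture**: decide
whether a perfused chamber can wash out cell-secreted (autocrine/paracrine)
ligands before the cells recapture them, verify that prediction with a 2D
transport simulation, and run the image-quantification and statistics
pipeline such an experiment needs — growth by colony-area fold increase,
reporter-positive fractions, replicate aggregation, t-tests, and qPCR
standard-curve relative expression. A seeded synthetic-image generator with
exact pixel ground truth stands in for wet-lab micrographs, so the whole
measurement chain is testable end to end.

It is written for microfluidics and stem-cell labs designing perfusion
experiments (chamber height, flow rate, ligand and receptor parameters) and
for anyone who wants a validated, scripted version of the standard
"segment phase images → area fold increase → t-test" readout.

## The model

A chamber of height *h*, width *w*, length *L* is perfused at flow rate *Q*
(mean velocity *v* = *Q*/(*wh*)). Cells on the floor secrete a ligand
(diffusivity *D*) and recapture it via surface receptors with association
rate *k*<sub>on</sub> and areal density ρ<sub>R</sub> =
*N*<sub>R</sub>/(π*r*²*N*<sub>A</sub>) (one cell's receptors over its
projected disc). Three dimensionless groups decide the fate of the ligand:

- **Péclet number** Pe = *v·h*/*D* — convection vs. diffusion,
- **Damköhler number** Da = *k*<sub>on</sub>ρ<sub>R</sub>·*h*/*D* — binding
  vs. diffusion,
- **Pe/Da** — convection vs. binding.

Pe ≫ 1 and Pe/Da ≫ 1 put the chamber in the convection-dominated regime
where perfusion strips secreted ligand from the culture. The package also
reports the plane-Poiseuille wall shear τ = 6µ*Q*/(*wh*²) (the biological
limit on perfusion speed) and surface-to-volume ratios. The 2D simulator
solves the steady advection–diffusion balance with a reactive floor
(−*D*∂c/∂z = *q*<sub>s</sub> − *k*<sub>on</sub>ρ<sub>R</sub>·*c*) and
reports the **capture fraction** — the share of secreted ligand the cells
re-bind rather than losing to the outflow.

## Worked example

```python
from perfuse import transport as tr, chamber_sim as cs

setting, geom, ligand, receptor = tr.reference_design_point()
s = tr.summarize(setting, geom, ligand, receptor)
print(f"v = {s.v_mean_mm_s:.4f} mm/s, Pe = {s.peclet:.1f}, "
      f"Da = {s.damkohler:.3f}, Pe/Da = {s.pe_over_da:.0f}")
print(f"shear = {s.wall_shear_dyn_cm2:.2e} dyn/cm2, regime = {s.regime.value}")

grid = cs.default_grid()
floor = cs.FloorModel.uniform(grid.nx, qs=1.0,
                              uptake=tr.uptake_velocity(receptor))
v = s.v_mean_mm_s * 1e-3
field = cs.solve_steady(grid, v, ligand.diffusivity_m2_s, floor)
budget = cs.capture_fraction(field, floor, v, ligand.diffusivity_m2_s)
print(f"capture = {budget.capture_fraction:.3f}, "
      f"washout = {budget.washout_fraction:.3f}")
```

prints

```
v = 0.0293 mm/s, Pe = 73.3, Da = 0.132, Pe/Da = 555
shear = 7.04e-03 dyn/cm2, regime = convection_dominated
capture = 0.086, washout = 0.914
```

Read: at 33 µL/hr through a 250 µm × 1.25 mm chamber, transport is
convection-dominated (Pe ≈ 73 from the exact velocity; ≈ 75 with the
rounded 0.03 mm/s), receptor binding is weak relative to diffusion
(Da ≈ 0.13), and the simulator confirms the design intent: ~91% of
everything the cells secrete leaves the chamber, only ~9% is recaptured —
while wall shear stays three orders of magnitude below levels that perturb
stem cells.

The same analysis is available from the shell:

```sh
perfuse design                   # dimensionless report for the defaults
perfuse design --params my.yaml  # your chamber
perfuse simulate --sweep 0.1,1,10,75,750
perfuse synth --out imgs/ --seed 1     # synthetic image stacks + truth
perfuse quantify --images imgs/        # segment + measure
perfuse qpcr --records r.csv --standards s.csv --control static
perfuse e2e --out run/ --seed 1        # full side-by-side comparison
```

## Layout

- `src/perfuse/transport.py` — dimensionless design calculator
- `src/perfuse/chamber_sim.py` — steady 2D advection–diffusion–reaction solver
- `src/perfuse/synthetic_imaging.py` — colony scene generator + renderers
- `src/perfuse/quantify/` — segmentation, aggregation, t-test, qPCR
- `src/perfuse/pipeline.py`, `cli.py` — end-to-end drivers and the `perfuse` command
- `docs/methods.md` — model details, numerical choices, limitations
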