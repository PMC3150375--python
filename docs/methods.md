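# Methods

## 1. Dimensionless design analysis (`perfuse.transport`)

The chamber is treated as a parallel-plate duct (height *h* ≪ width *w*),
perfused with an aqueous medium (µ = 1.0×10⁻³ Pa·s at 37 °C). All physics
is computed in SI internally; the public interface uses bench units (µm,
µL/hr, cm²/s, M⁻¹s⁻¹, mm/s, dyn/cm²).

**Quantities.** Mean velocity *v* = *Q*/(*wh*); Péclet number
Pe = *v·h*/*D*; Damköhler number Da = *k*₍on₎·ρ_R·*h*/*D* with the receptor
density ρ_R = *N*_R/(π*r*²*N*_A) of a confluent monolayer — one cell's
receptors spread over its projected disc. A membrane-area convention would
lower ρ_R by the (unknown) spreading factor; the disc convention is the
default and the conservative choice for predicting washout, since it makes
binding look as strong as geometry allows. Wall shear is the
plane-Poiseuille value τ = 6µ*Q*/(*wh*²) times a multiplicative
`cell_factor` for the perturbation by attached cells; no published value of
that factor is adopted, so the default 1.0 reports the bare-wall shear and
the attached-cell estimate is treated as an order-of-magnitude statement.
Ligand diffusivity can be estimated from molecular weight by
Stokes–Einstein scaling, *D* ∝ MW^(−1/3), anchored at a 20 kDa / 10⁻⁶
cm²/s reference; for design decisions the fast end of the plausible
10⁻⁷–10⁻⁶ cm²/s band is used because it *under*-states convection's
advantage.

**Reference design point** (`reference_design_point`): 250 µm × 1250 µm ×
13 000 µm chamber, 33 µL/hr, 20 kDa ligand at *D* = 10⁻⁶ cm²/s,
10⁴ receptors per 10 µm-radius cell, *k*₍on₎ = 10⁶ M⁻¹s⁻¹. This yields
*v* = 0.0293 mm/s (Pe = 73.3; Pe = 75.0 when the conventionally rounded
0.03 mm/s is used), Da = 0.132, Pe/Da ≈ 555–568, τ = 7.0×10⁻³ dyn/cm², and
chamber surface-to-volume 1/*h* = 4 mm⁻¹ (vs. ≈ 0.785 mm⁻¹ for a 10 cm
dish with 10 mL of medium — the dish volume is an assumption, stated here
because it is not a measured quantity).

**Regime classification** uses configurable thresholds: convection-
dominated requires Pe > 10 *and* Pe/Da > 10; otherwise Da vs. 1 labels the
slower of diffusion and reaction. The thresholds express "≫ 1" as a
decade; they are defaults, not physical constants.

## 2. Steady chamber transport (`perfuse.chamber_sim`)

A 2D *x–z* cross-section of unit width (lateral gradients neglected,
*w*/*h* = 5) carries plane-Poiseuille flow *u*(*z*) =
6*v*(z/h)(1−z/h). The steady balance *u·∂c/∂x* = *D*∇²c is closed by:
inlet (x = 0) *c* = 0 (fresh medium), outlet (x = L) zero diffusive flux
(fully developed), ceiling no-flux, and a Robin floor condition on
cell-covered nodes, −*D*∂c/∂z = *q*_s − *k*_up·*c* with uptake velocity
*k*_up = *k*₍on₎ρ_R. Binding is irreversible (no *k*_off, no receptor
saturation) — conservative for washout claims and consistent with building
Da from *k*₍on₎ alone. Secretion support can be restricted to a subset of
the covered floor (`secretion_mask`), which keeps the linear operator fixed
while sources vary; solutions then superpose exactly over disjoint sources.

**Discretisation.** Vertex-centred finite volumes on a uniform grid
(default 261 × 51, dx = 50 µm, dz = 5 µm): first-order upwind advection,
central diffusion, boundary fluxes applied on half control volumes. The
resulting sparse linear system is solved directly (UMFPACK-style LU via
`scipy.sparse.linalg.spsolve`); the problem is linear in *q*_s so no time
stepping or iteration is needed, and upwinding keeps the scheme stable at
the cell Péclet number (~15) the coarse grid implies. Because the flux
bookkeeping in `capture_fraction` reuses the discrete fluxes of the
assembly, the mass-balance error |secretion − capture − outflow|/secretion
closes to solver precision (~10⁻¹³); the budget includes the diffusive leak
through the inlet face, which is a real transport path at low Pe (scale
√(*Dh*/*k*_up)/*L* ≈ 5% at the design parameters). The inlet node column
carries the Dirichlet condition and is excluded from the floor budget.
Numerical guards: relative residual above 10⁻⁸ or concentrations below
−10⁻¹² of the field maximum raise an explicit failure.

Grid refinement (halving dx and dz) moves the design-point capture
fraction by < 0.1%, comfortably inside the 2% stability target. Secretion
rate *q*_s defaults to 1 in arbitrary units: every reported fraction is
*q*_s-independent by linearity, and absolute concentrations are reported in
units of *q*_s/*k*_up (no literature secretion rate is imposed).

**Validation oracles.** (i) Sealed chamber, no flow: floor concentration
must equal *q*_s/*k*_up exactly and capture = 1. (ii) Low Pe: the exact
closed form of the 1D depth-averaged model *Dh*c″ − *vh*c′ − *k*_up*c* +
*q*_s = 0 (agreement within 5%). (iii) High Pe: the residence-time
exponential 1 − exp(−*k*_up*L*/(*vh*)) (agreement within 20%); at Pe = 75
the 2D capture is 0.086 vs. 0.089 for the exponential. The *depth-averaged*
model is deliberately not used at high Pe: secreted ligand travels in the
slow near-floor streamlines, so the well-mixed average (0.044) understates
recapture by ~2×.

## 3. Synthetic micrographs (`perfuse.synthetic_imaging`)

Scenes emulate adherent mESC colonies in chamber micrographs: rotated
ellipses with a low-order (orders 2–5) Fourier perturbation of the boundary
radius, placed by dart throwing so centres keep ≥ 0.8 × the sum of
effective radii apart — colonies arise from separate seed cells, and the
separation also prevents deeply nested layouts whose merged rims enclose
background pockets that no hole-filling segmenter could resolve. Colony
sizes are lognormal (CV 0.35). The realised rasterised area is matched to
the requested fraction by a global rescale loop (±10% relative); the
default target of 7.5% coverage is typical attachment density ~24 h after
seeding. Growth multiplies colony areas about fixed centres (a grown scene
therefore contains its parent exactly), bisecting the scale to hit
fold × area; targets are capped at 0.95 ("confluency") with a flag, and
colonies may clip the frame edge only when an in-frame configuration cannot
reach the target. Reporter positivity is assigned colony-wise (seeded
order) with one partially positive colony, a concentric sub-region bisected
to land the requested reporter fraction within ±0.02.

Rendering: phase images are background 0.45, textured interior 0.40
(Gaussian texture, σ 0.03, 1.5 px correlation), bright rim ("phase halo")
0.75 over a 3 px band, plus white Gaussian noise (default σ 0.02, all on a
[0,1] scale, quantised to 8- or 16-bit); fluorescence is 0.05 background /
0.70 on reporter pixels plus noise. Every artifact is a pure function of
(seed, parameters).

**What this does and does not emulate.** The generator reproduces the
features the segmentation pipeline keys on — bright rims, enclosed
interiors, noise, growth, controllable reporter area — with exact ground
truth. It does *not* model optical point-spread, uneven illumination,
debris, cell-scale texture, or colonies whose halo is broken; passing the
recovery tests therefore demonstrates the pipeline's correctness on clean,
well-formed inputs, not its robustness to degraded real-world imagery.

## 4. Quantification (`perfuse.quantify`)

Phase segmentation, in fixed order: white top-hat (disk radius 15 px,
decomposed footprint) to extract bright features → percentile contrast
stretch (1st–99th) → Otsu threshold (a fixed threshold is available for
reproducibility across batches) → removal of objects < 64 px → hole
filling. Area is reported as a pixel fraction: every downstream readout
(fold increase, reporter fraction) is a ratio, so µm calibration is
unnecessary (a µm-per-px option exists for absolute areas). Fluorescence is
segmented by stretch → Otsu *without* the top-hat, with a minimum Otsu
inter-class separation of 0.10 below which the channel is declared
signal-free (never threshold pure noise into a mask). The reporter fraction
intersects the fluorescence mask with the phase mask, guaranteeing a result
in [0, 1]. Degenerate inputs: constant phase images yield an empty mask
with a warning; an empty phase mask yields a flagged NaN reporter fraction.

Aggregation follows the experimental hierarchy image → chamber →
condition-within-experiment → across experiments, reported as mean ±
sample s.d. (n−1). Conditions are compared with the unpaired two-tailed
equal-variance Student's t-test (pooled variance, n_a+n_b−2 d.f.);
zero-variance degenerate cases return p = 1 (equal means) or p = 0 with an
infinite t (unequal).

qPCR: per-gene least-squares standard curve Ct = m·log₁₀(amount) + b over
≥ 3 dilutions, rejected if r² < 0.98 or m ≥ 0; efficiency 10^(−1/m) − 1
(m = −3.3219 ⇒ 100%). Amounts 10^((Ct−b)/m) are normalised to a reference
gene (Gapdh) within each sample and then to a control sample. Samples
missing the reference gene are skipped with a warning.

## 5. End-to-end contrast (`perfuse.pipeline.run_end_to_end`)

Mirrors a side-by-side chamber comparison: two conditions differing only in
growth rate (defaults 1.05×/day vs. 1.6×/day over 5 days, i.e. a stalling
vs. a rescued culture, an ≈8-fold final contrast), 3 independent
experiments × 3 chambers × 4 images, every image synthesised, segmented and
aggregated as above, and the day-5 fold increases compared by t-test.
Frames are 256 × 256 (unit tests use 192 × 192 and fewer images) rather
than camera resolution — the statistics are identical and one full run
stays under a minute. With the default contrast the test detects the
difference at p < 10⁻⁷; with identical conditions p is uniform on (0,1)
and the run is asserted non-significant, not "p ≈ 1".

## 6. Known limitations

- The transport model is steady, 2D, Newtonian, with irreversible binding;
  no receptor trafficking, ECM competition, transient start-up, or 3D
  side-wall effects.
- The attached-cell shear correction is a free factor; only the bare-wall
  shear is computed from first principles.
- First-order upwinding adds numerical axial diffusion ~*u*·dx/2; at the
  design point axial transport is advection-dominated by 4 orders of
  magnitude, so the effect on capture is negligible (verified by
  refinement), but very coarse grids at extreme Pe should be refined.
- Segmentation parameters are defaults, not fits to any instrument;
  correctness is established against generator ground truth, not against
  annotated micrographs.
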