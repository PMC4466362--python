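# npquant

Quantification of nanoparticles internalized by adherent cells, from 3D
super-resolution fluorescence stacks, together with the transport simulation
that says how many particles ever reached the cells.

## The problem

When submerged cells are exposed to a nanoparticle suspension, three numbers
matter for dose-response work and they are all different:

* the **administered dose** — particles added to the medium (number per mL);
* the **delivered dose** — particles that reach the cell monolayer by
  gravitational settling and Brownian diffusion during the exposure;
* the **intracellular dose** — particles actually internalized per cell.

For silica particles of 25-85 nm, the intracellular dose can be counted
directly by imaging whole cells in 3D: a plasma-membrane label and a
nuclear-lamina label are imaged in confocal mode (lateral PSF FWHM ≈ 277 nm),
and the particle label in STED mode (FWHM ≈ 76 nm), so that individual
particles and small agglomerates appear as separable objects.  This package
implements that whole counting chain, a synthetic ground-truthed stack
generator to validate it, and the dose arithmetic connecting the three dose
levels.

## What is in the package

`src/npquant/`:

| module | what it does |
| --- | --- |
| `synthetic` | ground-truthed 3-channel stacks: half-ellipsoid A549-like cell phantom on a substrate, particle/membrane/lamina emitters, separable 3D Gaussian PSF, Poisson shot noise, Gaussian read noise, detector saturation |
| `preprocess` | Gaussian PSF kernels and Richardson-Lucy maximum-likelihood deconvolution (optional in the pipeline) |
| `cellmask` | whole-cell ROI from the membrane channel: Otsu threshold → ball-radius-2 closing/opening → 3D + per-slice cavity filling → component selection (largest, or by manual polygon) |
| `detect` | particle objects in the NP channel: Otsu threshold, Gaussian-smoothed marker-free watershed (default σ = 2.0 µm), the 5% intensity-discard rule, lateral object widths, strict inside-cell classification, per-cell summaries |
| `psfmetrics` | line-profile extraction and Gaussian fits: FWHM = 2√(2 ln 2) σ ≈ 2.3548 σ with per-parameter uncertainties |
| `dosimetry` | delivered dose: 1D sedimentation-diffusion PDE (below) with Stokes settling and Stokes-Einstein diffusion, plus effective agglomerate spheres |
| `agglomerates` | particle counts inside wide objects under 1D/2D/3D packing models |
| `dose` | number↔mass conversion, surface coverage, volume occupancy, intracellular concentration, uptake efficiency, BET surface-area regression |
| `io`, `pipeline`, `cli` | TIFF/CSV/YAML formats with provenance, the end-to-end driver, and the `npquant` command-line tool |

`analysis/` holds numbered driver scripts (simulate → count → widths →
dosimetry → dose report) that write their tables under `results/`.

### The delivered-dose model

The suspension column of height *h* above the monolayer obeys

    ∂C/∂t = D ∂²C/∂x² + V ∂C/∂x,   0 ≤ x ≤ h,

with *x* measured up from the cells, a perfectly absorbing bottom
(C(0, t) = 0: particles touching the monolayer stay), a zero-flux top, and a
uniform initial concentration.  The coefficients come from Stokes' law and
the Stokes-Einstein relation,

    V = g (ρ_p − ρ_m) d² / (18 µ),        D = k_B T / (3 π µ d),

and an agglomerate of N primaries at packing fraction φ is an effective
sphere with d_agg = d (N/φ)^{1/3} and ρ_agg = φ ρ_p + (1 − φ) ρ_m.  The
deposited number fraction is 1 − (mass left in the column)/(initial mass);
the solver is an implicit finite-volume scheme (1000 cells, geometrically
graded time steps) that conserves mass to ~1e-12 and matches the short-time
closed form 2√(Dt/π)/h to 0.1%.

### The packing models

A detected object of lateral width *w* built from particles of diameter *d*
contains an estimated

    n₁ = round(w/d),   n₂ = round(0.91 (w/d)²),   n₃ = round(0.74 (w/d)³)

particles if it is a chain, a plate (hexagonal packing 0.91) or a compact
cluster (close packing 0.74); each estimate is clamped below at 1.  Objects
narrower than the single-particle cutoff (150 nm for 85 nm particles, 75 nm
for 25 nm) count as one particle.

## Worked example

Delivered dose for 25 nm silica (density 1.8 g cm⁻³) after a 5 h exposure of
1 mL medium over a 5 mm column at 37 °C:

```bash
$ npquant dosimetry --diameter-nm 25 --hours 5
{
  "fraction": 0.15054470726693892,
  "fraction_pct": 15.054470726693891,
  "per_area_cm2": 6925056534.27919,
  ...
  "diffusivity_m2_s": 2.4559086704384577e-11,
  "settling_velocity_m_s": 3.681174924924925e-10,
  "mass_balance_rel_error": 3.0863115882406866e-12
}
```

15.1% of the administered 9.2 × 10¹⁰ particles mL⁻¹ reach the monolayer —
6.9 × 10⁹ particles per cm².  Settling is negligible for 25 nm particles
(V ≈ 0.4 nm s⁻¹); the deposition is diffusion-dominated.

The full imaging pipeline on a synthetic cell with 117 internalized 85 nm
particles and 30 membrane-attached ones (the default scene):

```bash
$ npquant run-all --seed 1 --out run1/
{
  "n_objects_inside": 121,
  "objects_per_um2": 0.46282908678083623,
  "projected_area_um2": 261.4356,
  "n_objects_total": 149,
  "mean_intensity_inside": 247.10802422810823
}
```

— 121 counted against 117 true internalized particles (+3.4%), with the
attached particles excluded by the strict inside-ROI test.
`analysis/02_count_particles.py` runs the same chain on the full-size
phantom for both particle sizes and writes `results/counts.csv`
(119 counted / 117 true for 25 nm, 337/338 for 85 nm at seed 1).

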