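# Methods

This note documents the models behind `npquant`, the parameters that matter,
the numerical choices, and what the synthetic-data validation does and does
not demonstrate.

## Synthetic acquisition model

**Cell phantom.** An adherent cell is a half-ellipsoid resting on the
substrate plane z = 0 (semi-axes a_x, a_y, a_z; defaults 13 × 10.5 × 5.6 µm,
volume (2/3)π a_x a_y a_z ≈ 1600 µm³, a typical adherent alveolar epithelial
cell) with an ellipsoidal nucleus strictly inside.  The membrane is the
curved surface plus the basal ellipse; the lamina is the nucleus surface.  A
voxel is interior iff its center is inside, which makes the voxelization
unambiguous.

**Emitters.** Particles are point emitters (the fluorophores sit inside the
particle; at 25-85 nm the finite label distribution adds little to the
imaged width, and the generator does not model it).  Internalized emitters
are placed uniformly in the interior at a configurable margin from the
membrane (default in the validation scenes: 600 nm — cytosolic particles,
not membrane-adjacent ones).  Membrane-attached emitters sit half a
diameter outside the membrane, at sites weighted by the upward component of
the surface normal: deposited particles arrive by settling, so the
attachment flux scales with the vertical projection of the surface element.
Clusters of 2-4 particles are regular simplexes with edge length d (all
members pairwise in contact); membrane and lamina labels are dense surface
emitters (defaults 80 µm⁻²).

**Optics and detection.** The PSF is a separable 3D Gaussian parameterized
by its lateral and axial FWHM.  Lateral FWHMs are 76 nm (STED mode, 30 nm
pixels) and 277 nm (confocal mode, 60 nm pixels); the axial FWHM is not
constrained by those settings and defaults to 600 nm in both modes; the
z-step is 130 nm.  Expected counts are background + Σ brightness × PSF
sampled at voxel centers (the PSF integrates to 1, and a rendered emitter
conserves its photon budget to <1%).  Poisson shot noise is applied to the
expected counts, then Gaussian read noise (0 for the photon-counting STED
detector, 3 counts for the confocal channel), then hard clipping at the
detector maximum — the testable analog of an avalanche photodiode shutting
down on very bright agglomerates.

**Relative brightness.** The theoretical dye content of an 85 nm particle
exceeds a 25 nm particle's by orders of magnitude, but measured per-object
intensities are far closer (quenching, incomplete coupling); the validation
scenes use 1.2e4 (25 nm) vs 2.0e4 (85 nm) expected photons so that both
kinds of objects are comfortably above background without saturating.

**What the generator does not emulate:** depletion-beam physics (the STED
PSF is an effective Gaussian), spectral crosstalk, drift and scanning
artifacts, photobleaching over the stack, out-of-focus haze beyond the
Gaussian axial tail, and textured cytoplasmic autofluorescence.  Passing the
recovery tests therefore shows the segmentation logic is correct under the
stated noise model, not that it is robust to every real-microscope artifact.

## Segmentation and counting

**Cell ROI.** Otsu's threshold (256 bins over the data range) on the
membrane channel, morphological closing then opening with a ball of radius
2 voxels (closing first preserves thin membrane signal), hole filling in 3D
plus 2D filling of every slice along all three axes (a cavity truncated by
the stack border is open in 3D but closed in its 2D sections), then the
largest connected component, or the components intersecting a user polygon
when several cells share the field.  The thresholded membrane voxels are
always contained in the output mask.

**Known bias.** The mask follows the *outer* edge of the blurred membrane
signal, so it is inflated outward by roughly the PSF half-width (~0.15 µm
laterally, ~0.3-0.4 µm axially).  For a 1600-2000 µm³ cell this inflates the
mask volume by ~8-10%, and it is the route by which an occasional
membrane-attached object is misclassified as internalized (measured
precision of the inside test on validation scenes: 0.96-0.99).

**Particle objects.** On the NP channel: Otsu threshold T; Gaussian
smoothing with a configurable sigma (default 2.0 µm); watershed of the
inverted smoothed image restricted to the thresholded foreground, with
markers at the regional minima of that masked relief, so every foreground
component yields at least one object and touching blobs split at internal
minima.  Two numerical guards matter:

* the relief is quantized to 256 levels over its dynamic range before
  minima are taken — at σ = 2 µm the smoothed field is nearly flat and
  float-level ripple along thin, axially elongated blobs would otherwise
  mint spurious markers and fragment single particles;
* a channel whose maximum does not exceed T by at least 15 robust
  background SDs (median absolute deviation of sub-threshold voxels) is
  declared empty — Otsu has no notion of "no signal" and would otherwise
  segment the upper tail of pure shot noise.

Objects whose *peak* voxel intensity is below T + 0.05 (I_max − T) are
discarded (the rule targets noise-floor objects, and the peak — not the
mean — is what noise inflates); I_max is the channel maximum, so the rule is
invariant under intensity rescaling, and the globally brightest object can
never be discarded.  Labeling uses 26-connectivity.  With σ = 2 µm the
watershed cannot split agglomerates tighter than the smoothing scale — the
sigma is kept configurable, and the separation behavior (two spots merge
below ~0.5 PSF FWHM, separate at ≥4 FWHM) is identical at σ = 0.15 µm and
σ = 2 µm for well-separated scenes.

**Width and inside test.** An object's lateral width is the maximum
center-to-center extent of its voxels in the z-slice nearest its centroid,
plus one pixel (a single-voxel object is one pixel wide); sub-resolution
objects measure the imaged PSF footprint (~80-140 nm in STED mode).  An
object is internalized iff *every* voxel lies in the cell mask — strict
containment deliberately undercounts borderline objects rather than
counting attached ones.  Objects at the lateral stack border are kept;
objects touching the z extremes are kept but flagged.

## Delivered dose

The 1D convection-diffusion problem (absorbing bottom, closed top, uniform
start) is solved by an implicit finite-volume scheme: upwind advection,
half-cell diffusive flux against the sink at the wall, backward Euler on a
geometric time grid (first step 10 ms).  Defaults: 1000 cells, 800 steps —
the 5 h deposited fraction changes by <0.01 percentage points when both are
doubled, the short-time pure-diffusion closed form 2√(Dt/π)/h is matched to
0.1%, and the discrete mass balance closes to ~1e-12.  Deposition is
monotone in time, diffusivity and settling velocity by construction
(M-matrix).  Runtime ~0.05 s per solve.

Medium defaults: T = 310.15 K, ρ_m = 1.00 g cm⁻³, µ = 7.4e-4 Pa s (a
standard assumption for serum-supplemented aqueous media at 37 °C), column
height 5 mm with 1 mL volume.  Particle default density 1.8 g cm⁻³
(amorphous silica).  Cluster packing defaults to random close packing
(0.637).

**Sensitivity worth knowing.** In the diffusion-dominated regime the
deposited *fraction* scales as 1/h while the deposited *number per area*
(2 C₀ √(Dt/π) at short times) is nearly independent of h.  The effective
height of 1 mL depends entirely on the vessel: 5 mm corresponds to a 2 cm²
base, while 1 mL in a standard 12-well (~3.8 cm²) is a 2.6 mm column and
nearly doubles the fraction (15.1% → 28.6% for 25 nm at 5 h;
`analysis/04_dosimetry.py` tabulates both geometries).  Reported fractions
should always be read against an explicit column geometry.

A related quantity — the delivered concentration in a thin near-cell layer,
fraction × C₀ × h_column / h_layer — is reported by the dose chain only
implicitly (per-area density); spreading the deposited number into a 10 µm
layer is a presentation choice, not a transport result, and is left out of
the acceptance outputs.

## Dose arithmetic

Number↔mass conversion uses the measured (electron-microscopy) diameter of
the specific particle lot rather than its nominal size: 9.2e10 particles
mL⁻¹ of d = 24 nm silica at 1.8 g cm⁻³ is 1.2 µg mL⁻¹, which the nominal
25 nm diameter does not reproduce.  Surface coverage is the projected
monolayer fraction per_area × πd²/4 and is reported even when >1 (flagged
supersaturated).  The BET surface-area regression 143.2 − 1.505 d (m² g⁻¹)
is a linear fit over calibration sizes 23-72 nm; outside that range the
value is returned with an out-of-calibration flag, and a non-positive
extrapolation raises.

## Validation scenes and what they show

The end-to-end checks place 117 and 338 internalized particles (the
per-cell means of the two studied sizes) at ≥4 PSF-FWHM spacing plus 20
membrane-attached particles in the default phantom, render all three
channels with noise, and run the full chain.  Recovered inside counts are
within 5% of truth with precision ≥0.95 (measured: +2.6% / 0.975 and +0.3%
/ 0.994 at the test seeds).  The ≥4-FWHM spacing makes this a test of
segmentation, classification and bookkeeping — not of how counting degrades
in dense scenes, where the watershed under-separates (recall falls
monotonically as spacing shrinks below the PSF scale).

## Degenerate inputs and conventions

Constant images have no Otsu threshold (error); empty NP channels give an
empty object list (not an error); an empty cell mask after filtering is an
error with the threshold in the diagnostic.  Coordinates are physical nm,
axis order (z, y, x), 0-based voxel indices, voxel position = voxel center;
lengths are nm internally, with µm/mm/cm only at I/O boundaries and unit
suffixes in all field names.  All randomness flows through
`numpy.random.default_rng(seed)`; equal seeds give bit-identical stacks and
byte-identical output files.
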