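# Methods

This note documents the models, algorithms, defaults and design choices in
`epimech`, and what the synthetic-data generators do and do not emulate.

## Nanoindentation (`epimech.indentation`)

**Model.** Spherical Hertzian contact, F = (4/3)·E_eff·√R·δ^{3/2}, with the
effective Young's modulus E_eff = E/(1−ν²) as the single stiffness
parameter — no Poisson ratio is assumed or reported. Displacements are piezo
positions (µm); because the cantilever is soft (default 0.025 N/m for a
20 µm probe), its deflection F/k is a non-negligible fraction of the travel,
so the indentation depth is always compliance-corrected,
δ = (z − z_c) − F/k. As k → ∞ the corrected fit converges to the
uncorrected one (tested).

**Contact point.** The instrument convention implemented is a joint
(z_c, E_eff) fit restricted to samples with force at most 30% of the
maximum load (`load_fraction=0.30`). Given z_c, the model is linear in the
Hertz prefactor, so E_eff is profiled out in closed form and the search is
one-dimensional: a coarse pass over the sample grid followed by bounded
scalar minimisation between the neighbouring grid points. A brute-force
grid search is kept in the public API (`grid_search_contact_point`) as the
reference the optimiser is tested against. Whether the joint fit should act
on the force or its derivative inside the low-load window was an open
choice; the force-based joint fit is used and documented here.

**Quality gate and aggregation.** R² is computed against the mean-force
null on the fitted segment only (contact point to 2.5 µm depth); fits with
R² ≤ 0.95 are rejected. Matrix scans are aggregated as mean over accepted
indentations within a scan, then mean over scans; means (not medians) are
used at both levels.

**Oscillatory moduli.** Linearising Hertzian contact around the operating
indentation δ_op gives the contact stiffness S = 2·E·√(R·δ_op), hence
E\* = (F_amp/δ_amp)·e^{iφ}/(2√(R·δ_op)); E′ = Re E\*, E″ = Im E\*. The
sweep frequencies carry through untouched (defaults 1, 2, 4, 10 Hz).

## Brillouin analysis (`epimech.brillouin`)

**Spectral fit.** The damped-oscillator Lorentzian
I(ω) = (I₀/π)·Γω_B²/((ω²−ω_B²)²+Γ²ω_B²) is even in ω, so the same
three-parameter model fits the Stokes (ω<0) and anti-Stokes (ω>0) windows;
parameters are constrained positive, initialised from the window maximum and
a half-maximum width estimate. Voxel values are the arithmetic mean of the
two sides; if one side fails to converge the valid side is used and the
voxel flagged single-sided. A voxel with both sides failed is excluded.

**Depth profiles.** Profiles (default 2 µm step over 80 µm) are smoothed
with a Savitzky–Golay filter (window 5 samples, order 2 — the filter is part
of the procedure, the constants are this package's defaults). Candidate
peaks must span at least 3 samples (6 µm) and exceed 0.02 GHz prominence;
the prominence floor is an addition that suppresses false peaks from noise
wiggles. The winning peak is refined by a Gaussian-plus-offset fit bounded
by the derivative's local maximum before and local minimum after the
candidate; if refinement fails or leaves the window, the smoothed sample
value is used. Without a peak, the drop onset is the first index where a
centred 3-point moving average of the derivative falls below −0.005 GHz/µm,
and the plateau value is the mean of the smoothed shifts before onset.
Profiles with neither feature are flagged indeterminate and excluded, the
analogue of manual outlier screening. All constants are exposed as keyword
arguments.

**Maps.** 8-bit rendering maps min→0 and max→255 linearly with half-up
rounding (an epsilon guards exact halves against binary float error); the
inverse mapping is stored so byte images round-trip within half a
quantisation step. Region statistics report mean, sample SD (ddof = 1) and
voxel count for core, interstitium (complement) and whole map; the
count-weighted core/interstitium means recombine exactly to the whole-map
mean for every mask. Instance segmentation of the byte image is out of
scope: the pipeline consumes label masks from an external segmenter or the
generator's truth masks.

## Monolayer imaging (`epimech.monolayer`)

* **Nuclei density** — Gaussian smoothing (σ = 2 px) → threshold (Otsu by
  default) → watershed on the distance transform with `peak_local_max`
  markers (minimum separation 5 px) → components ≥ 20 px counted; density is
  count over field area.
* **Cell height** — per sampled foreground column of a binary x–z
  cross-section, height = (max z − min z + 1)·axial pixel size; ten columns
  uniformly spaced across the foreground span by default. Fixed-and-mounted
  samples shrink axially; no correction is applied, heights are reported as
  measured.
* **Shape factor** — q = P/√A per cell (the alternative circularity
  4πA/P² was considered and rejected as the package-wide definition; q is
  the form used throughout). P and A come from the sub-pixel marching-squares
  boundary polygon; the closed contour is smoothed with a 5-point circular
  moving average before measuring because the raw staircase overestimates
  curved perimeters by ~5% (a square's q then reads 4.00 and a disk's 3.55
  at the tested resolutions, converging with resolution). Cells touching the
  image border are excluded as truncated.
* **Ratios** — junctional/cytoplasmic: cell ROIs are slimmed by binary
  erosion (disk, 3 px); the complement of the slimmed ROIs is the junctional
  band; the ratio of band mean to slimmed-ROI mean is returned per image.
  Nuclear/cytoplasmic: nuclear mean over nucleus labels; nuclei are zeroed
  and the rest thresholded; cytoplasmic mean over the supra-threshold
  non-zero region. Both return exactly 1.0 on uniform images; adding a
  constant offset pulls ratios toward 1 (documented non-invariance).
* **Thresholded junctional mean** — mean grey value over supra-threshold
  pixels only.
* **Extrusion counting** — frames are registered to the first frame by
  integer-pixel translation using plain (unnormalised) cross-correlation;
  phase-normalised correlation proved unreliable on smooth low-contrast
  fluorescence backgrounds. Aligned frames are Gaussian smoothed, overlaid
  in a maximum-intensity projection over time, thresholded and components
  ≥ 4 px counted. The default threshold is mean + 10·SD of the projection,
  which stays above the projected background texture when no event occurred
  while bright extrusion spots exceed it by a wide margin.

Otsu is the default wherever an automatic threshold is needed; every
threshold accepts a numeric override or a `"sigma:K"` rule.

## POS internalisation (`epimech.pos`)

Stacks are (z, y, x) with z increasing apically. The apical surface is the
top face of each column's uppermost supra-threshold actin voxel,
z = (iz+1)·dz; columns without signal are missing, and a surface with more
than 50% missing columns is rejected as unreliable. The cut-off is the
single scalar mean of the finite heights — the mean-surface convention is
kept deliberately rather than a local per-column comparison. Particles are
26-connected supra-threshold components of at least 4 voxels; centroids use
voxel centres and volume is voxel count × voxel volume. Classification is
by centroid against the cut-off; a centroid exactly at the cut-off counts
as bound, the conservative tie-break against over-counting internalisation
(classification by any-voxel-below-cutoff was the alternative; centroid is
the implemented and recorded convention). Apical actin area triangulates
the height map restricted to a fixed slice subset (two triangles per grid
cell); a flat surface gives exactly the lateral footprint, and roughness
can only increase the area.

## Statistics (`epimech.stats`)

Technical replicates are averaged (arithmetic mean) into one value per
(biological replicate, condition, measurement) before testing. The paired
t-test acts on differences b − a (t positive when b exceeds a); the ratio
paired t-test is the paired t on log-transformed values — natural logs,
though the statistic and p-value are base-independent — and requires
strictly positive data. Zero difference (or log-ratio) variance raises a
dedicated error rather than returning an infinite statistic. One-way ANOVA
uses the standard between/within decomposition. No multiple-testing
correction is applied; star annotations follow the usual thresholds
(\* p<0.05 to \*\*\*\* p<0.0001). Null simulations (n = 4 pairs, 2000
replicates) confirm both paired tests reject at 4.1–6.0% at α = 0.05.

## Synthetic data (`epimech.synthetic`)

Every generator is a pure function of its parameters and a seed
(bit-identical repeats) and returns the dataset plus a JSON-serialisable
ground-truth dict. Noise is additive Gaussian with SD = `noise_level` ×
signal amplitude, except the z-profile generator, which takes an absolute
`noise_ghz` because depth-scan noise is naturally quoted in GHz. Defaults
encode the study conditions: 694/513 Pa moduli regimes, 20 µm probe at
0.025 N/m driven 6 µm, ~6.3 GHz doublets with Γ = 0.5 GHz, 2 µm z-steps
over 80 µm, 50 × 50 µm maps at 1.5 µm step, ~3000 cells/mm² fields, 9.1 µm
apical surfaces, 2% extrusion fractions. Where no instrument noise
magnitude is documented, defaults (2% of force amplitude, 0.005 GHz on
profiles, 2–5% on images) were fixed once at levels typical of the
respective instruments and kept.

Constructions worth noting:

* **Hertz curves** solve the compliance coupling exactly per sample
  (bracketed root find), so the generated force is the model's own fixed
  point, not an approximation.
* **Z-profiles** place a Gaussian bump on a logistic gel→medium transition
  whose amplitude is solved so the on-grid maximum equals the requested
  peak value exactly; `with_peak=False` yields the monotone transition
  alone.
* **Shift maps and monolayer fields** are Voronoi tessellations of seeded
  points — a geometric fixture motivated by the honeycomb organisation of
  the epithelium, not a biophysical model. Only geometry and intensity
  matter to the quantifications under test. The monolayer's junctional band
  is drawn as the complement of the slimmed cell ROIs — the same
  construction the ratio measurement uses — so the drawn band and the
  measured junctional region coincide pixel for pixel and the truth ratio
  is exact by construction.
* **Nuclei** sit on a jittered grid with a guaranteed non-overlap margin;
  requesting densities beyond the packing limit raises an error. Counts are
  exact (`round(density × area)`), which is what makes paired-field density
  comparisons exact in expectation.
* **POS stacks** snap the actin slab to the voxel grid so the recovered
  cut-off equals the requested height exactly; particle truth records the
  rasterised (not nominal) centroid and voxel volume, and placement
  enforces centroid margins of at least one voxel from the cut-off plus
  non-touching separations.
* **Extrusion movies** combine a static smooth texture (the monolayer
  pattern registration locks onto; 10% of background by default) with
  per-frame photon noise and two-frame bright spots placed with minimum
  mutual distance; optional cumulative integer drift exercises the
  alignment step.

**What the generators do not emulate** — optics and spectrometer physics,
camera noise statistics (shot noise is approximated as Gaussian), pigment
absorption, real cell-shape variability beyond Voronoi geometry, apoptosis
kinetics, particle adhesion dynamics, or segmentation errors of the external
instance segmenter (its role is played by ground-truth masks). Passing
recovery tests therefore demonstrates the correctness of the quantification
algorithms under controlled conditions, not robustness to every artefact of
real microscopy data.

## Problem sizes and numerics

Test and acceptance runs use desk-scale inputs chosen as the package's
standard fixtures: 241-sample curves, 1601-sample spectra, 41-sample
profiles, ~33×33 maps, 316×316 px fields with 300 cells, 160×96×96 voxel
stacks with 50 particles, 60-frame movies, 2000-replicate null simulations.
Nonlinear fits use `scipy.optimize.curve_fit` with positivity bounds;
failed spectral fits are flagged rather than raised; the contact-point
refinement uses bounded Brent with 10⁻⁶ µm tolerance. Degenerate inputs
(blank fields, constant profiles or maps, empty regions or classes, zero
variance) are either flagged in the result or raise typed errors, as listed
in each docstring.

## Known limitations

* The contact-point search assumes a single contact event and a monotone
  loading segment; adhesion (JKR/DMT), unloading analysis and substrate
  corrections are out of scope.
* Brillouin shifts are not converted to longitudinal moduli (that would
  require refractive index and density maps).
* The junctional band is a fixed-width morphological construct; it does not
  follow intensity ridges, matching the fixed-geometry macro it mirrors.
* Per-cell junctional partitioning (watershedding the band to individual
  cells) is not needed for the per-image ratio and is not implemented.
* The shape-factor perimeter is contour-based; at very low resolution
  (cells of a few pixels) the isoperimetric bound can be violated by
  discretisation, which is why border cells and sub-resolution regions
  should be excluded upstream.
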