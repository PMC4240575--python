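# Methods

## The measurement model

The package treats a ToF angiography volume as a scalar field I(x) on an
anisotropic grid (default 0.31 × 0.31 × 0.40 mm) in which vessels are
bright tubes on a darker background. All stages operate per VOI; all
physical quantities are in mm / mm² / mm³, standardized totals per cm³ of
VOI.

### Vessel enhancement

Second derivatives are taken as Gaussian-derivative convolutions with
per-axis kernel width σ/spacing (voxel units), converted to per-mm², and
scale-normalized by σ^γ with γ = 2. Working in physical units per axis —
rather than resampling to an isotropic grid — avoids interpolation bias at
the 0.31/0.40 mm anisotropy. Boundary handling is reflection. scipy's
truncated derivative kernels are corrected to zero sum (truncate = 6 plus
subtraction of the residual kernel-sum times the image), making the
Hessian exact on constant images; a flat volume scores exactly zero.

Eigenvalues are sorted by magnitude per voxel. The default score is the
standard three-eigenvalue 3D form with α = 0.5, β = 0.5 and the
structuredness constant c set, per scale, to half the maximum Hessian
Frobenius norm over the VOI. A two-eigenvalue compatibility mode
(`as_printed_2eig`) applies the 2D-style ratio R_B = |λ₂|/|λ₃| to the two
largest-magnitude eigenvalues, with S still over all three; it exists
because descriptions of this pipeline sometimes print the two-eigenvalue
form even for volumetric data, and the mode makes that reading executable.
The multiscale response is the voxelwise max; the winning scale is kept
for diagnostics.

Default scale ladder: σ ∈ {0.15, 0.3, 0.6, 1.2} mm, spanning the ~300 µm
diameter detection limit of 7T ToF up to large pial vessels. Vesselness is
reported on a 4096 arbitrary-unit scale (12-bit convention) so thresholds
are comparable to ToF intensity practice.

### Segmentation and object measurement

Thresholding is strict (`value > t`, documented so runs are
bit-reproducible); the default threshold is 2200 arb. units with the
expectation that it is adjusted per VOI, as in the original operator
protocol. Components are labeled at 26-connectivity (configurable to
6/18), renumbered deterministically by raster order of first voxel, and
objects under 4 voxels are dropped. Volume is voxel count × voxel volume.
Surface is the sum of exposed-face areas (a face is exposed when the
6-neighbor across it is background, outside the grid, or outside the VOI);
face-area summation is the anisotropy-correct reading of "multiply by the
voxel size", and the legacy surface-voxel count is reported alongside but
not used in any metric. Analysis is restricted to the VOI by clipping:
objects are cut at the VOI boundary and boundary faces count as exposed.

### Skeleton and branch graph

Thinning is the Lee et al. 6-subiteration simple-point erosion
(scikit-image implementation), run in voxel space; anisotropy enters only
in length measurement, matching the plugin lineage being reproduced.
Skeleton voxels are classified by 26-neighbor count: 1 endpoint, 2
internal, ≥3 junction; 26-adjacent junction voxels merge into one junction
node; branches are maximal internal paths between nodes, traced in
deterministic raster/offset order; branch length sums Euclidean steps
between voxel centers under the grid spacing. An isolated cycle
(anastomotic loop) is reported as one branch with no terminal nodes — the
choice matters only for anastomosed trees and is exercised by the torus
test. No spur pruning by default (again matching the plugin); a
`prune_below_length_mm` option exists for sensitivity analysis.

### Morphometry and statistics

Mean branch length is total branch length / branch count per VOI (not a
mean of per-object means). Mean diameter uses the uniform-cylinder model
d = 2√(V/(πL)); no defining formula is printed alongside the cohort
tables this package reproduces, but this model regenerates the printed
control mean diameter from the printed control V and L to 0.05% (and the
tumor value to ~1%), so it is adopted and documented as inferred. Empty
segmentations produce zero totals and *missing* means (never zeros), so
they cannot bias cohort statistics.

The Wilcoxon signed-rank test drops zero differences (classic convention;
Pratt available), uses midranks for ties, and computes the two-sided p by
full enumeration of sign assignments (dynamic programming over doubled
ranks) for n ≤ 25, otherwise a normal approximation with tie and
continuity corrections. Two-sided p is the doubled smaller tail, capped at
1. No multiple-testing correction is applied across the six metrics — the
report states this explicitly.

## The phantom generator

The generator emulates what the measurement chain sees in a 7T ToF VOI:
bright tubes of roughly 0.3–1 mm caliber on a darker background, either
dense/short/tortuous (tumor-like, with reduced vessel intensity — tumor
vessels lose ToF signal through slow, disturbed flow) or
sparse/long/straight (control-like white matter). It does **not** model MR
physics (no flow-dependent signal equations, slab boundaries, B1
inhomogeneity, pulsation or misregistration artifacts), vessel caliber
tapering, or contrast between arteries and veins. Passing recovery tests
therefore demonstrate that the measurement chain is unbiased on geometry
it was designed for — not that segmentation of clinical 7T data is solved;
on real data the operator threshold step absorbs artifact differences the
phantom does not contain.

Design choices:

* **Segment count is exact:** round(branch density × grid cm³) segments
  are always placed; placement failure raises rather than silently
  truncating.
* **Symmetric bifurcation:** a tip either spawns exactly two children or
  none (probability `bifurcation_prob`, subcritical < 0.5). A
  single-child attachment would create a degree-2 node that branch
  analysis rightly fuses, making ground-truth branch counts ambiguous;
  with 0-or-2 children, skeleton branch count equals segment count.
* **Stratified roots, minimum clearance:** roots are spread over jittered
  grid cells (vasculature supplies tissue quasi-uniformly; this also
  keeps sub-VOI counts stable in the variability experiment), and trees
  keep ≥ 2 voxels clearance so 26-connectivity cannot merge distinct
  trees.
* **Lengths and diameters** are truncated normals — lengths at 2 ×
  max(spacing) (sub-voxel segments are unrecoverable by any method),
  diameters at one in-plane voxel. Tumor preset: 3.5 /cm³, 3.8 ± 0.5 mm,
  ⌀ 0.803 ± 0.05 mm, tortuosity 0.35, bifurcation 0.4. Control preset:
  1.0 /cm³, 7.2 ± 1.0 mm, ⌀ 0.8541 ± 0.05 mm, tortuosity 0.1,
  bifurcation 0.1. Within-VOI SDs are modest by design; the published ±
  values are between-subject spreads and are used as such in the cohort
  simulator.
* **Tortuosity** displaces interior polyline points (≈ every mm)
  perpendicular to the segment by a bounded uniform amount, then rescales
  the polyline so its arclength equals the drawn length exactly — ground
  truth stays anchored.
* **Rasterization** marks a voxel as vessel iff its center lies within a
  segment's radius of the centerline polyline (anisotropic distances), so
  segment ends carry hemispherical caps; the caps roughly offset the end
  erosion of thinning, which is why skeleton lengths come out nearly
  unbiased. Voxelized truth (volume, face-count surface) uses the same
  conventions as the segmentation stage.
* **Noise:** Gaussian by default at SNR ≈ 20–26 (ToF magnitude data are
  Rician; a Rician option exists, but at these SNRs the Gaussian
  approximation is adequate and is used for the standard experiments).

## Experiment configuration and problem sizes

Recovery experiments run on ~10 cm³ phantoms (64³ voxels at ToF spacing),
the size of a typical tumor VOI; the variability experiment uses one
210×70×66 control phantom split into three ~12.4 cm³ sub-VOIs (the
published control VOIs averaged 13 cm³); the cohort simulator draws
per-subject generator parameters (between-subject SDs from the published
cohort tables, truncated to physical ranges) and tabulates ground-truth
morphometry of one tree per VOI — a deliberate desk-scale model in which
the pipeline's measurement fidelity is established separately by the
recovery experiments rather than re-run 4,800 times.

For phantom experiments the filter uses scales {0.3, 0.6} mm — σ
bracketing the ~0.4 mm tube radii the presets generate — and a vesselness
threshold of 1000 arb. units (score 0.24). The threshold plays the role of
the original protocol's per-VOI operator threshold and was fixed once by
QC inspection of a development phantom (background vesselness histogram
empty, vessel cross-sections full, segmentation matching the MIP), then
frozen for all experiments. On noiseless or high-SNR phantoms the
background response is near zero, so the exact value is uncritical within
a broad band; very low thresholds would admit the dilated support of
coarse scales (the classic Frangi halo), very high ones erode vessel
cross-sections.

## Numerical details

* Eigenvalues via LAPACK `eigvalsh` on stacked symmetric matrices;
  magnitude sort is stable, so exact ties keep LAPACK's ascending order.
* Divisions in R_A, R_B are guarded: vesselness is 0 wherever λ₃ = 0.
* Exact Wilcoxon enumeration works on doubled ranks (integers even with
  midranks); counts fit float64 exactly for n ≤ 25.
* Degenerate inputs: empty masks skeletonize to empty; empty cohorts or
  all-zero difference vectors are reported as "no evidence" (p = 1) at the
  cohort level but raise if the test is called directly; zero-vessel VOIs
  propagate missing means.
* Determinism: every stochastic step flows from an explicit integer seed
  through `numpy.random.Generator`; pipeline outputs carry a SHA-256 hash
  of the full configuration.

## Known limitations

* The skeleton underestimates total and mean branch length by ~3–6% on
  tumor-like geometry (junction voxel sharing, residual end effects);
  this is inherent to thinning-based morphometry and within the
  validation tolerances used here.
* Face-count surfaces overestimate smooth-tube lateral area by a factor
  approaching 1.5 (axis-aligned faces); comparisons must therefore use
  the same convention on both sides, as the truth tables do.
* The cylinder-model mean diameter is exact only for uniform-caliber
  networks; mixed calibers weight thick vessels by their volume share.
* The generator does not produce anastomoses (loops) — cycles are handled
  and tested, but not exercised by the presets.
* Very dense phantoms (> ~25% tube volume fill) are rejected rather than
  placed without clearance.
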