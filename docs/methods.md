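# Methods

## Scope and data model

The package analyzes dual-resolution X-ray CT of apple fruit: whole-fruit
scans at anisotropic low resolution (default spacing 0.5 mm between slices,
0.339 mm in-plane) for porosity mapping, and 6.6 µm isotropic sub-volumes
for cellular morphometrics. Volumes are signed 16-bit with axis order
(slice, row, col); all geometry downstream uses this convention. DICOM
series are read with per-file rescale slope/intercept applied, slices
ordered by position tag (instance number as fallback), and values clamped
to the int16 range with a warning rather than an error, since scanner
rescale headers vary. A missing slice-spacing tag falls back to the median
inter-slice position difference, then to 0.5 mm.

## Two-point porosity calibration

Porosity is an affine function of grey value fixed by two reference
materials: apple juice (pure cellular liquid, 0 % gas) and external air
(100 % gas). With anchors (g_juice, g_air) the model is the unique line
through (g_juice, 0) and (g_air, 100); the defaults are 49 and −1007 on the
int16 scale, shipped as configuration rather than constants because the
anchors are cultivar- and protocol-specific. The raw model is deliberately
unclamped — voxels denser than juice (seeds, stone cells) map to negative
porosity and remain diagnosable — and clamping to [0, 100] is an explicit
flag applied when a porosity map is produced. One grey unit corresponds to
100/1056 ≈ 0.095 porosity points under the default anchors, which is the
quantization floor every round-trip test uses. Validation follows the
random spot-check idiom: n voxels sampled uniformly without replacement
(default n = 10), predicted vs known porosity scored by R². Because no
per-voxel ground truth exists for real scans, validation targets synthetic
truth volumes.

## Fruit segmentation and anatomical regions

Scene segmentation thresholds the grey histogram with Otsu's criterion.
The implementation is in-package (cumulative-moment form over a 256-bin
histogram, threshold = bin edge, ties to the lowest edge) because the
package's tests require exact equivalence with an exhaustive reference
search; a guard rejects scenes whose two Otsu classes differ by less than
100 grey units (an all-air field of noise should not segment — real
tissue sits ~800 grey units above air). Components are 26-connected, which
is robust to thin diagonal bridges at 339 µm; components below a minimum
volume (default 50 mm³) are discarded, interior holes are filled in 3D so
gas cavities belong to their fruit, and labels are ordered by size.

Region classification bands the porosity map per fruit: seeds 0–10 %, core
5–15 %, cortex 15–30 %, cavity ≥ 90 % (not exactly 100, to absorb noise and
partial-volume voxels). Before banding, porosity is averaged over a 1 mm
ball restricted to the fruit mask; unsmoothed voxelwise banding on noisy
maps yields salt-and-pepper labels. The seed and core bands overlap by
construction; the overlap is resolved geometrically — seeds and core are
central structures, so band-ambiguous voxels are only seed/core-eligible
within an inner radial zone (default 0.35 of the fruit's equivalent
radius), and inside that zone the overlap interval splits at its midpoint
(smoothed porosity < 7.5 → seed). Tissue voxels matching no band take the
label of the nearest assigned voxel (anisotropic Euclidean distance). The
result partitions every fruit mask exactly, which the tests assert.

Whole-fruit porosity is the arithmetic voxel mean over the fruit mask,
cavity included by default: the fruit's internal void space is part of its
porosity, and excluding it is an explicit option that requires a region
map. Line profiles interpolate trilinearly (standard for anisotropic
medical volumes); group comparisons use one-way ANOVA with Tukey HSD at
α = 0.05 (scipy); macro–micro association reports both Pearson and
Spearman, as there is no reason to presume linearity.

## Microstructure

A 0.5 mm cubic ROI at 6.6 µm shows three phases: bright cell bodies, an
intermediate cell-wall/juice matrix, and dark gas pores. Contrast
enhancement rescales the 1st–99th percentile window to [0, 1] (monotone, so
class structure is preserved); adaptive histogram equalization is available
but not default. Thresholding for blob detection uses a three-class
multi-level Otsu: the lowest class is gas, the highest is cell material.
A single two-class threshold cannot isolate both polarities in a
three-phase image — whichever side of one cut you take, the matrix phase
contaminates it — so the two-class form is only a fallback for genuinely
bimodal inputs. Touching objects are split by watershed on the Euclidean
distance transform with peak markers at least one minimum-expected-diameter
apart; objects outside the configured diameter range are dropped, and
objects touching the ROI boundary are kept but flagged.

Each blob's size is its equivalent-sphere diameter from voxel volume.
Morphometrics use interior blobs for mean diameters; cell density applies
a first-order edge correction (boundary-touching cells weigh 0.5), which is
simpler and less wasteful than a guard zone in a 76-voxel cube. Pore volume
ratio is total pore voxel volume over ROI volume, and ROI porosity is that
ratio in percent; `measure_roi_porosity` provides the same quantity by
direct voxel counting of the gas class, without object splitting. The
sunny/shady comparison is a paired two-sided t-test per metric, difference
reported as sunny − shady in percentage points (the "+1.71 % higher
porosity" convention is read as percentage points, not relative percent).

## Synthetic phantoms

**Whole-fruit phantoms** voxelize an ellipsoidal fruit with a core cylinder,
a ring of dense seed ellipsoids, and gas-filled carpel cavity lobes; paint
order (cortex → core → cavities → seeds) nests the anatomy. Default region
porosities are seed 4, core 10, cortex 22, cavity 100 %, with 1-point
zero-mean jitter inside tissue regions to exercise the smoothing in region
classification. `solve_cortex_for_mixture` voxelizes once and solves the
single linear equation that makes the voxel-weighted region mixture hit a
requested whole-fruit mean exactly (rejecting solutions outside the 15–30 %
cortex band). The forward model maps porosity back to grey values through
the calibration, adds Gaussian noise (default σ = 10 grey units), rounds
and clamps to int16; background voxels are air. Multi-fruit scenes place up
to three phantoms on a row with fixed gaps, so collisions are impossible by
construction.

**Cellular phantoms** pack non-overlapping bright cell spheres into the ROI
cube by random sequential adsorption (RSA): diameters N(69, 2) µm by
default, minimum clearance 2 µm, every sphere fully interior (≥ 1 voxel
margin) so no truth object touches the boundary. Strict-interior RSA
saturates near a 0.28 volume fraction in a 0.5 mm cube, so the default
packing target is 0.25; an exact cell count can be requested instead
(e.g. 200 cells ≈ 0.275 packing, which needs a reduced clearance and a
larger rejection budget). Pore spheres (default N(30, 4) µm) avoid cells
but may merge with one another — intercellular gas channels are
interconnected, and strict pore–pore RSA cannot reach realistic gas
fractions — and insertion tracks the voxel union incrementally, so the
achieved gas fraction equals the requested target to within one sphere.
Grey levels are cells 1500, matrix 800, pores −900 with σ = 60 noise:
well-separated phases, which is what the three-class threshold assumes.
RSA spheres rather than a physical tessellation is a deliberate trade:
exact per-object ground truth for validating detection and morphometrics,
at the cost of parenchyma realism (no polyhedral cells, no wall network,
no partial-volume voxels). Passing tests therefore demonstrate that the
measurement chain is unbiased on resolvable, well-contrasted objects — not
that it handles real tissue texture, beam hardening, or reconstruction
artifacts, which are out of scope.

**Quality tables** draw each trait as x = l1·F1 + l2·F2 + ε from two unit-
variance latent factors, scaled to realistic units (12 traits: four
seed/cell traits on F1, three morphology/porosity traits on F2, five
sensory traits moderately on both). Treatment levels shift factor means;
the default crop-load factor moves F1 by ∓1 SD (high/standard/low).
Identifiability required one non-obvious design choice: if all bridging
(group B) traits load both factors with the same sign, every trait becomes
positively correlated and PC1 rotates toward a general factor, destroying
the planted pattern at any sample size. The defaults therefore alternate
the sign of B's F2 loading and give group A a small compensating cross-
loading (−0.0735) so the planted cross-products cancel exactly and the
principal axes coincide with the factors in expectation.

## Quality index

Z-scoring uses the population σ by default (sample mode available). PCA is
computed on the standardized matrix; loadings are reported as trait–
component correlations, and each component's sign is fixed so its largest-
magnitude loading is positive (reproducibility across BLAS builds). The
weight rule w_i ∝ Σ_{j≤k} |loading_ij|·varfrac_j over the first k = 2
components is one concrete reading of "weights follow loading strength";
an |PC1|-only strategy is provided as an alternative. Weights are
nonnegative and sum to 1, so Q = Σ w_i z_i has mean 0 over samples and is
invariant to any affine rescaling of raw trait columns. Group assignment
compares |PC1| and |PC2| loadings with a dominance margin of 0.35 —
roughly twice the loading standard error at the sample sizes used — since
a smaller margin lets rotation noise push balanced traits into A or C.
With these defaults the planted memberships are recovered for ≈94 % of
traits across 20 seeds at 90 samples; at 27 samples the PC rotation noise
(set by the eigen-gap) makes balanced-vs-dominant classification
noise-limited for bridging traits, which is a genuine small-sample limit
of loading-based grouping, not of the implementation.

## Problem sizes and numerical choices

Recovery studies run at sizes chosen to keep the full suite comfortably
reproducible on a single CPU: whole-fruit recovery at 128³ voxels (≈0.5 M
fruit voxels; recovered mean within 0.01–0.03 points of the planted
24.70 % at σ = 10 noise), single-ROI morphometrics at the native 76³, and
the 100-replicate paired-offset study at a reduced 0.2 mm / 40 µm-cell
geometry with gas fraction measured by voxel counting (the blob route and
the voxel route agree to < 0.01 points on these phantoms; the single-seed
headline run uses the full 0.5 mm blob pipeline). Determinism: every
generator takes an explicit seed and derives child seeds from
`numpy.random.default_rng`; identical seeds give bit-identical volumes and
identical end-to-end summaries (timestamps are deliberately excluded from
the run summary).

## Known limitations

No projection-space physics: phantoms are painted in reconstructed space,
so beam hardening, scatter, rings, and partial-volume blur are absent. The
two-point calibration assumes the juice and air references bracket tissue
attenuation linearly; multi-point or nonlinear calibration is out of
scope. Region banding assumes the porosity hierarchy generalizes; fruits
with disorders (watercore, internal browning) violate the bands. Blob
morphometrics assume near-spherical objects; elongated cells would bias
equivalent diameters. The CLI covers the standard paths only; the library
is the full surface.
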