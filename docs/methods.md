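# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `vertebrome`. It describes what the code computes and why
the defaults are what they are; every number quoted as an empirical
result here is one the test suite or `scripts/acceptance.py` computes.

## Volumes and calibration

Volumes are 3D grids of raw integer intensities with an isotropic voxel
size in µm (21 µm is the working default for whole adult fish; 10.5 µm
for high-resolution scans). Axis convention: axis 0 dorsoventral (dorsal
at index 0), axis 1 mediolateral, axis 2 anteroposterior (anterior at
slice 0, the DICOM slice axis); the mapping is carried explicitly in
`axis_labels`.

Tissue mineral density is obtained from raw intensity x as

    TMD (mgHA/cm³) = (x / divisor) · slope + intercept

with defaults slope = 281.706, intercept = −195.402, divisor = 4096,
taken from hydroxyapatite-phantom scanner calibration. The constants live
in configuration, not in DICOM rescale tags, because the mapping is
defined on raw exported values; the divisor is configurable because its
relation to the detector bit depth is scanner-specific. Negative
calibrated densities (raw values below ≈2841) are retained rather than
clamped — TMD statistics are only ever computed over above-threshold bone
voxels, which calibrate positive in practice.

Reorientation about the anteroposterior axis uses trilinear interpolation
with zero fill; voxel mass is conserved to within 1% for rotations of an
interior structure (asserted in tests).

## Thresholding

Fish differ markedly in overall mineralization, so a per-specimen
threshold is computed: a user outline drawn on a maximum-intensity
projection is extruded along the projection axis, voxels outside it are
zeroed, and the IsoData (iterative intermeans) fixed point
T = (mean(<T) + mean(≥T))/2 is found on a 256-bin histogram of the
remaining nonzero voxels of the full 3D stack. The result is multiplied
by a correction factor, default 0.73, for more permissive capture of
weakly mineralized structures. Foreground is intensity ≥ threshold
(inclusive; stated once and used everywhere). Our IsoData agrees with
scikit-image's `threshold_isodata` to within two histogram bins on
bimodal samples (cross-checked in tests); a constant histogram is an
error, not a threshold.

## Vertebral separation

Seed lines are drawn in the mid-sagittal plane between adjacent centra
and extruded across the full mediolateral extent into separation planes
(n+1 boundaries for n vertebrae). For each boundary: plane voxels are
zeroed; 26-connected components are labeled within a local window
extending 10 voxels to either anteroposterior side; component voxel
counts are tallied on the two sides of the plane; if the plurality
component on each side is distinct (an empty side — e.g. anterior to
vertebra 1 — counts as trivially separated, a tie as not separated), the
boundary is accepted, otherwise both endpoints are extended outward along
the segment's own direction by 2 voxels and the test repeats. Extension
that reaches the volume boundary without separating raises an error
naming the seed. Voxels between consecutive accepted boundaries receive
consecutive labels by component centroid. The extension step (2 voxels),
vote window (10 voxels) and voxel-count (rather than component-count)
voting are design choices exposed as parameters; 26-connectivity is used
throughout because thin arches fragment under stricter connectivity. A
manual cut tool (`apply_cut`) severs spurious bridges (ribs touching fin
rays); whole connected components can be reassigned between vertebrae
(`assign_components`), which re-checks the one-label-per-component
invariant.

## Element segmentation

Within one vertebra, using the four endpoints of its anterior and
posterior boundary lines: the neural arch is everything strictly dorsal
to the line through the two dorsal endpoints; the centrum is the
quadrilateral prism through all four points, dilated by a buffer (default
5 voxels, applied as a Euclidean dilation in the dorsoventral ×
anteroposterior plane) minus the neural arch; the haemal arch/ribs are
the remainder. The three masks partition the vertebra exactly — asserted,
not assumed. The buffer exists to capture the centrum endplates fully;
its cost is that arch tissue within the buffer of the centrum
quadrilateral is attributed to the centrum, which is why the phantom
(below) models a small soft-tissue clearance at the haemal arch base.

## The 25 measures

Per element (Cent, Neur, Haem) and for the union mask (Tot — computed on
the union, not averaged from elements): volume (voxel count × voxel³,
exact by definition), surface area (count of foreground voxels with ≥1
face-adjacent background neighbor × voxel², the perimeter-voxel
estimator; biased low relative to meshed surfaces, so values should not
be compared across estimators), mean and population-SD of local thickness
and of calibrated TMD over the element's voxels; plus centrum length
(anteroposterior distance between boundary-line midpoints). Surface areas
are reported in physical units (µm²).

Local thickness is the model-independent largest-inscribed-sphere
diameter: Euclidean distance transform → distance ridge (centers whose
sphere lies within a face-neighbor's sphere are dropped) → sphere
propagation in order of decreasing radius. Distances are center-to-center,
so one voxel is subtracted from the diameter to place boundaries at voxel
faces: an isolated voxel measures 1 voxel, an n-voxel slab n voxels, and
a digital ball of radius 10 measures its true diameter within 5%.
Expected residual bias for thin curved shells is below half a voxel.

Phenome tables are tab-separated, one row per vertebra, columns under
long names (`CentrumTMDs`, `VertebralVolumes`, …) so that cohort tables
in that dialect parse directly; missing vertebrae are NaN, never
zero-filled.

## The global test

For two groups, the binary group indicator y is the response and the k
per-vertebra values of one measure are covariates. With e = y − ȳ and
X the n × k matrix, the score statistic is Q = eᵀXXᵀe/k, the sum of
per-vertebra components (x_jᵀe)²/k. Covariates are not standardized, so
high-variance vertebrae carry proportionally more weight — the behavior
of the reference formulation of this test. The default p-value is the
exact Gaussian-rotation law of the scale-free ratio T = Q/(eᵀe):
P(εᵀ C(XXᵀ/k − T·I)C ε ≥ 0) for ε ~ N(0, I), a mixture of chi-squares
over the eigenvalues of the centered matrix, evaluated by Imhof's
characteristic-function inversion (adaptive quadrature for single tests;
a vectorized fixed log-grid rule, cross-checked to ~1e-4, for Monte-Carlo
batches). This ratio form was chosen over the plug-in-variance mixture
because calibration simulations at n = 3/group (the regime these screens
run in) show it holds its size almost exactly — empirical type-I error
0.0097 at α = 0.01 — whereas the plug-in form is severely conservative
at such tiny n. Exact permutation (enumeration when the number of label
assignments is ≤ 20,000, sampling otherwise) is available and is verified
against brute-force enumeration in the tests. Per-vertebra component
p-values are single-covariate versions of the same test; "significant
vertebrae" are reported unadjusted at α = 0.05. Analyses default to the
16 anterior-most vertebrae, restricted to the vertebrae present in all
retained fish; fish missing more than 25% of the window are excluded with
a warning.

Skeletal barcodes are standard scores: per measure, z = (value − m)/s
with m, s pooled over all vertebrae and fish of the control population
(pooling across vertebrae is deliberate — the barcode shows where a fish
departs from the control column as a whole). Correlation profiling turns
each (measure, vertebra) pair into a vector across fish and reports
absolute Pearson correlations with per-pair exclusion of missing fish,
ordered by average-linkage clustering of 1 − |ρ| (ordering is cosmetic).
Royston's H screens each measure for multivariate normality across
vertebra subsets (it requires n > k, hence subsetting, and combines
per-variable Shapiro–Wilk deviates with an equivalent-degrees correction
for correlation); for k = 1 it reduces exactly to Shapiro–Wilk.

## Monte-Carlo power analysis

One measure across k = 16 vertebrae is modeled as MVN(µ, Σ) with µ and Σ
(denominator n−1) estimated from a control cohort; rank deficiency
(n ≤ k) is expected and handled by eigen-decomposition sampling with
negative eigenvalues clipped at zero (clipping warns). Simulated mutants
share Σ and shift means by d_i·σ_i, with d_i either uniform (= d) or a
linear ramp from 0 at vertebra 1 to d at vertebra k. Each replicate draws
fresh control and mutant cohorts (sensitivity) or two control cohorts
(specificity) and applies three procedures: the global test on vertebrae
1..16, a two-tailed Welch t-test of vertebra 2, and a Welch t-test of the
per-fish mean over 1..16. Defaults: 10,000 replicates, n = 3/group,
α = 0.05, all driven by one seed and bit-reproducible. Measures that fail
the Royston screen on the reference control cohort (Cent.Th, Neur.Th,
Haem.Th.sd, Cent.Le) are flagged in `EXCLUDED_FEATURES` for exclusion
from feature sweeps. The companion FDR estimate is the equal-prior
two-urn value α/(α + sensitivity).

At these group sizes the Welch tests are mildly conservative (the
Satterthwaite degrees of freedom at n = 3 + 3 are small), so their
WT-vs-WT specificity sits near 0.995 at α = 0.01 while the global test
sits at 0.990; both are "specificity ≈ 0.99" at two decimals, and
neither procedure is anti-conservative.

`reference_wt_model()` provides a deterministic synthetic control model
for self-contained simulation studies: mean vertebral TMD rising from 450
to 550 mgHA/cm³ along the column (the range observed in adult wild-type
vertebrae), inter-fish SD of 5% of the mean, and AR(1) correlation
ρ = 0.7 between vertebrae. These are fixed study conditions, not tuning
knobs; absolute sensitivities under this model differ from those under a
particular experimental cohort's covariance (its long-range correlations
are stronger than AR(1) decay), but the qualitative ordering —
pattern-level testing dominates, ramped effects reduce global sensitivity
and collapse single-vertebra tests — is reproduced and asserted.

## Allometric normalization

Each feature y is modeled against standard length x by y = a·xᵇ, fit as
OLS on log y vs log x (exact on noiseless power-law data; b̂ unbiased
under multiplicative log-normal noise, both asserted). Models are fitted
per feature and per vertebra on a control ontogenetic series;
convergence simulations show b̂ varies by <10% for subsamples of ≥10 of a
16-fish series. Normalization maps y to a reference length:
y* = y·(x*/x)ᵇ. Isometric expectations are b = 3 for volumes and TMC,
b = 1 for thickness and length (b = 2 for surface area). TMD is never
normalized directly: TMC = Vol·TMD·10⁻¹² (mgHA) and Vol are normalized
independently and normalized TMD is their ratio, so deviations of
mineralization from geometric growth survive normalization. SD-type
features scale with their parent's exponent (TMD.sd with the effective
exponent b_TMC − b_Vol), preserving relative dispersion. Only control
phenomes are transformed — mutant growth may follow different allometry —
and the reference length defaults to the mutant group's mean standard
length. The CV used to evaluate normalization is population-SD/mean.
Normalizing to a length and back is the identity (asserted).

## The spine phantom

The generator emulates the anatomy the segmenter must handle: hollow
hourglass centra (outer radius 14 voxels tapering to 0.8× at the waist,
4-voxel wall, 30 voxels long, 4-voxel gaps), dorsal half-annulus neural
arches seated on the centrum rim (radius 12, wall 3), and ventral haemal
arches that are enlarged (radius +6) on the anterior half of the column
to mimic rib-bearing precaudal vertebrae. The haemal arch is offset 6
voxels ventrally from the centrum wall, emulating the soft-tissue
separation at its base and keeping the 5-voxel centrum buffer from
annexing it. Default intensities calibrate to 492 (centrum) and 389
(arches) mgHA/cm³; Gaussian noise (SD 150 raw units) is added over the
whole grid. All randomness flows through one seed. Ground truth — label
map, element masks, analytic measure table, ideal gap-center seed lines —
is computed from the geometry, except volumes, where the voxel count is
the definition. Simulated operator error jitters seed endpoints uniformly
within the intervertebral gap.

What phantom-based validation shows: exact bookkeeping (volumes, TMD,
labels), sub-voxel thickness accuracy on walls, Dice > 0.9 element
recovery under ideal and jittered seeding, and end-to-end determinism.
What it does not show: robustness to beam hardening, partial-volume
blur at real bone-soft-tissue interfaces, dysmorphic vertebrae, or
touching specimens — real microCT effects the phantom does not model.

## Problem sizes and reproducibility

Test-suite simulations use 3-vertebra noiseless phantoms for exact
checks, a 5-vertebra noisy phantom for end-to-end runs, and 1,500–10,000
Monte-Carlo replicates depending on the tightness of the assertion; the
acceptance script uses the full 10,000 replicates at k = 16, n = 3/group.
Every output table is written with a JSON sidecar embedding the full
run configuration and package version; reruns with the same inputs are
bit-identical.

## Known limitations

- Statistical reanalysis of the original experimental cohorts requires
  their per-fish phenome tables (not redistributable here); the
  corresponding acceptance tests fail until the tables are placed under
  `data/reference_cohorts/`.
- The surface-area estimator is voxel-face counting, not meshing.
- The separation-plane search assumes boundaries roughly transverse to
  the anteroposterior axis; severely kinked columns may need manual cuts.
- No beam-hardening correction; no automatic (unseeded) boundary
  detection; no penetrance/expressivity (non-Gaussian) phenotype
  simulation.
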