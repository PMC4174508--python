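# Methods

`pvi-scarpipe` quantifies ablation injury of the left atrium (LA) on
cardiac MR at two stages after pulmonary-vein isolation (PVI): acute edema
and injury at 24 hours (T2-weighted and late-gadolinium-enhancement
imaging) and established scar at 30 days (LGE). This note records the
models, the measurement rules, the synthetic phantom that stands in for
patient data, and the numerical choices a maintainer would need to know.

## Measurement model

**Edema enhancement ratio (EER).** On T2W images, wall water content is
expressed as the ratio of mean LA-wall ROI signal to mean LV-myocardium ROI
signal,

    EER = SI_wall / SI_LV.

The positivity threshold is derived from control (pre-ablation)
measurements as mean + k·SD with k = 3; with the control cohort statistics
0.87 ± 0.18 this gives 1.41, used in practice as EER > 1.4. Wall ROIs are
small (~60 voxels), matching how ostial wall signal is sampled on clinical
reads.

**Contrast-to-noise ratio (CNR).** On LGE images, enhancement of a target
ROI against the blood pool is

    CNR = (SI_target − SI_blood) / σ_air,

where σ_air is the sample SD of signal in an air-space ROI (the noise
estimate). Wall tissue is called enhanced at CNR > 3.5 and no-reflow
(microvascular obstruction, MVO) at CNR < −3.5. CNR may legitimately be
negative.

**Wall thickness.** A caliper along a ray through the posterior wall at the
LA equator: the wall is the bright plateau between blood pool and air, and
each boundary is the half-maximum crossing between the plateau peak and the
adjacent baseline, located by sub-step linear interpolation on a trilinear
profile (0.25 mm steps). Accuracy is limited to roughly one in-plane voxel;
on the phantom the measurement runs ~1 voxel thin because the wall shell is
painted from a voxel-center distance transform. Because the caliper is
deterministic, its repeat-read reproducibility on the phantom is nearly
perfect (ICC ≈ 1) — unlike a human observer, whose variability this
surrogate does not model.

**Enhancement volumetry.** The LA cavity trace is an input (the phantom
supplies it; on patient data it is drawn manually). The wall search region
is the shell within `shell_mm` (default 12 mm) outside the cavity.
Candidate voxels above the EER or CNR threshold are kept, connected
components (26-connectivity) with caliper diameter ≤ 3 mm are discarded,
and the surviving volume is reported as a percent of the cavity volume.
Two refinements matter in practice:

* *Island diameter is measured in-plane by default.* With 4–5 mm slices,
  the 3D Feret diameter of any two vertically adjacent voxels already
  exceeds 3 mm, which would make the small-island rule vacuous; measuring
  the caliper slice-wise matches a reader working on axial images. The 3D
  definition remains available (`ThresholdPolicy.island_diameter_mode`).
* *No-reflow must be enclosed.* Extracardiac air inside the search shell is
  as dark as MVO. When a cavity trace is available, dark components that are
  26-connected to the shell's outer surface are rejected: genuine no-reflow
  is enclosed by enhancing tissue, air communicates with the outside.

## 16-segment model

Each of the four PV ostia (LSPV, LIPV, RSPV, RIPV) contributes four
quadrants — anterior, posterior, superior, inferior — covering wall
territory within 10 mm of the ostium center; overlapping territories are
resolved by nearest ostium (lexicographic tie-break). Quadrants are centered
on the anatomical directions: the offset from the ostium, orthogonalized
against the vein axis, is classified by its angle in the per-vein
(anterior, superior) frame with boundaries on the diagonals; boundary
points go to anterior/superior. The frame is built by Gram–Schmidt from the
patient +y (posterior→anterior) and +z (inferior→superior) axes.

A segment is called injured when the enhanced (or merged enhanced∪MVO)
tissue inside its territory is *sizable*: it must admit an inscribed
diameter above 3 mm (twice the maximum of the distance-to-background
transform of the within-territory voxel set). Requiring inscribed width —
rather than any intersecting voxel — keeps a hairline of interpolated
signal along a quadrant boundary (an artifact of comparing registered
scans) from flagging the neighboring segment, and is the per-segment
reading of the "sizable territory, > 3 mm" rule. MVO counts as injury at
24 hours and, having evolved into scar, at 30 days.

Thirty-day scans are acquired in a different patient position; per-quadrant
calls on them use the segment model carried through the *recovered*
registration transform, i.e. matched locations are established by
registration exactly as on patient data.

## Registration

Rigid 3D registration of the 30-day LGE to the 24-hour LGE maximizes Mattes
mutual information (32 histogram bins by default) with a three-level
multiresolution pyramid (shrink 4/2/1, smoothing 2/1/0 mm) and a
regular-step gradient-descent optimizer over full, regularly sampled voxel
data — no stochastic subsampling, so results are bitwise repeatable. The
implementation is SimpleITK behind the package's `RigidTransform`
interface; a hand-written joint-histogram MI evaluator independently
verifies that the returned transform never scores below its initialization
(the initialization is returned otherwise). Trilinear interpolation is used
for intensity, nearest-neighbor for ROI/label propagation. MI is invariant
under affine intensity rescaling of either image; registration inherits
this.

On the default phantom cohort the planted transform (5° + ~5 mm) is
recovered to ≲0.6° and ≲1.2 mm — within one in-plane voxel.

## The synthetic phantom

The phantom makes every stage testable without patient data. It is
deliberately geometric, not anatomical:

* **Geometry.** The LA cavity is an ellipsoid (default radii 21×17×15 mm)
  with four cylindrical PV stubs (radius 5 mm, length 12 mm) at
  left/right–superior/inferior directions; the wall is the shell of
  configurable thickness around the cavity (7.0 mm baseline, thickened to
  10.7 mm at 24 h, resolved by 30 d); an LV-myocardium slab occupies
  inferior slices as the T2W reference; everything else is air. Grids
  default to 1.5×1.5×5 mm (T2W) and 1.4×1.4×4 mm (LGE).
* **Signal.** Units are arbitrary — every statistic downstream is a ratio.
  Per-segment cohort draws set the wall signal: EER ~ N(0.87, 0.18²)
  uninjured and N(1.52, 0.38²) edematous; scar CNR ~ N(8.2, 3.6²) at 24 h
  and N(11.4, 4.1²) at 30 d; uninjured wall on LGE sits at CNR
  N(−1.0, 0.6²) (mildly dark nulled tissue — placed above the −3.5
  no-reflow threshold so that the rule-based MVO detector, a surrogate for
  the visual read, remains meaningful); the MVO core is fixed at CNR −6,
  planted near the ostium and enclosed by scar, clear of the epicardial
  surface. Additive white Gaussian voxel noise (T2W SD 4 ≈ 4% of the LV
  reference; LGE noise equals the air SD, the CNR unit) approximates
  high-SNR magnitude MR; Rician statistics are not modeled.
* **Injury truth.** Sixteen labels in {none, edema_only, edema_and_scar,
  scar_only, mvo}. The default pattern places combined edema+scar in most
  quadrants with one MVO, isolated-finding, and spared segment each —
  ablation encircles the ostia — and the cohort generator shuffles
  placement and varies the spared count per subject.
* **Time-points.** Generated independently apart from the planted rigid
  transform; no biological evolution is modeled beyond switching each
  segment's signal class (edema resolves by 30 d; MVO becomes scar). The
  30-day scan emulates a *repositioned acquisition*: the transformed
  geometry is painted natively on the moved grid. (Interpolating the
  24-hour-frame voxelization instead would smear scar across 4-mm slices
  and bias measured 30-day volumes upward by ~20%.) Consequently the
  round-trip property — resampling the 30-day scan under the planted
  transform reproduces the aligned volume — holds exactly away from tissue
  boundaries (<1% NRMS error for voxels >1 voxel from any edge), with the
  residual confined to the boundary shell (voxelization).
* **Planted truth for volumetry** is the threshold rule applied to the
  noise-free painted means: the volume that is truly above threshold given
  the drawn signals. Measured-vs-true discrepancies therefore isolate the
  effects of noise, ROI-estimated references, and the island filter.

What passing phantom tests does **not** show: performance on real anatomy
(curved thin walls, partial volume, surface coils, motion), reader
variability, or the spatial correlation structure of real lesions. The
phantom's cohort heterogeneity is limited to lesion count and thickness
draws, so between-subject volume correlations are much weaker than in
patients.

## Cohort statistics

Diagnostic accuracy pools per-quadrant calls across subjects into a 2×2
table against the 30-day LGE reference (segments not assessable in either
reading are dropped and counted). Sensitivity/specificity/accuracy carry
Wald normal-approximation CIs clipped to [0, 1], with Wilson intervals
reported alongside; the Wald form is the default because it best matches
conventional reporting for these proportions. Association uses Pearson's
chi-squared on the 2×2 table (1 df, no continuity correction by default);
agreement uses Cohen's kappa; reproducibility of continuous measurements
uses ICC(2,1) (two-way random, single measure, absolute agreement) and
Bland–Altman bias ± 2 SD; volume relationships use Pearson correlation with
the t-transform p-value; group comparisons use the pooled-variance two-
sample t-test. No multiple-testing correction is applied: the comparisons
are few and pre-specified, and uncorrected p-values are the reporting
convention for this analysis. All
formulas are written directly and are cross-checked in the test suite
against independent brute-force implementations and against
scipy/statsmodels/sklearn/pingouin.

## Problem sizes and determinism

The standard verification cohort is 7 synthetic subjects × 16 segments
(112 quadrant calls) on the default grids, with registration per subject —
about 20 s end to end. Every random quantity (thickness draws, injury
patterns, signal draws, voxel noise, ROI sampling) derives from a single
seed via spawned generators, and results serialize with sorted keys and
fixed float precision, so identical seeds give byte-identical result files.
Planted-truth call accuracy is checked against exact Poisson-binomial
acceptance regions (central ≥99.7%) built from the per-segment analytic
normal-CDF call probabilities, which degrades gracefully where the
binomial-SD band would collapse (oracle probabilities near 0 or 1).

## Raw-measurement tables

`supplementary_io` reads deposited raw-measurement sheets (CSV first-class,
XLSX via openpyxl) into typed rows — unparseable cells are reported by row
and column, never dropped — and recomputes every derivable summary
statistic: cohort EER/CNR means ± SD, per-quadrant diagnostic accuracy,
kappa, percent of quadrants with findings, and the thickness comparison.
Statistics whose inputs are absent are reported as `None`, never
fabricated. A subject-exclusion list handles, e.g., a subject imaged with a
different contrast agent. Because the deposited workbook cannot be shipped
here, the test suite validates the recomputation on a synthetic equivalent
(`tests/s1_synthetic.py`) drawn from the published cohort distributions
with an internally consistent call contingency; tests additionally check
the printed values exactly whenever a real workbook is placed at
`data/raw_measurements.xlsx`.

## Known limitations

* The phantom wall is painted from a voxel-center distance transform, so
  caliper thickness reads ~1 voxel thin and cavity volumes carry a
  one-voxel-shell uncertainty.
* The rule-based MVO detector requires the planted no-reflow to be enclosed
  by enhancing tissue; transmural no-reflow touching the epicardial surface
  would be rejected as air.
* Clinical reads can leave quadrants non-assessable, so published
  diagnostic proportions need not correspond to integer counts over the
  nominal segment total; the confusion operation therefore tracks dropped
  segments explicitly, and the synthetic raw table uses internally
  consistent counts throughout.
* Image-mode ingestion covers volumetric segmentation from NIfTI inputs;
  16-segment calls on patient data additionally require ostium coordinates,
  which no released dataset accompanies here.
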