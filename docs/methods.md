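# Methods

`adipoquant` measures white-adipocyte size and count in H&E-stained sections.
In routine 5 µm paraffin sections the lipid droplet dissolves during
processing, so each adipocyte appears as a large, nearly unstained lumen
bounded by a thin eosin-stained membrane. The pipeline therefore reduces to a
lumen-detection problem: classify each pixel as *fat lumen* versus *any
stained tissue*, convert the lumen mask into discrete cell objects, and
summarise their geometry. Every quantitative threshold is expressed in µm or
µm² and converted through the image's µm-per-pixel calibration, so behaviour
is independent of scan resolution.

## Synthetic tissue generator

Real validation slides are patient material and are not distributable, so the
package carries its own generator that emulates subcutaneous adipose tissue
at the scale used for validation: 2×10⁶ µm² fields holding ≈300 whole cells
(mean area ≈4–5×10³ µm², mean circular-equivalent diameter ≈70–80 µm).

Construction:

1. **Point process.** Uniform dart throwing with a minimum-spacing rejection
   rule (spacing 0.62/√ρ, well below the hexagonal packing limit) on a
   margin-expanded region, so border Voronoi territories are bounded. The
   point rate carries a geometric edge correction
   ρ·WH/((W−d̄)(H−d̄)), with d̄ the nominal cell diameter, so that the
   expected number of *whole* cells matches `target_density × area / 10⁶`
   after border-clipped cells are dropped (regions are annotated around
   whole adipocytes only).
2. **Tessellation.** Voronoi partition of the points; each territory is inset
   by half the membrane thickness (default 4 µm, a visually thin crisp
   membrane at the rendered 1 µm/px).
3. **Size jitter.** Each cell is scaled about its centroid by the square root
   of a lognormal area factor (median fill 0.85 of the inset territory,
   CV default 0.45 — matching the right-skewed adipocyte size distributions
   whose SD/mean in real cohorts is ≈0.45–0.6) and clipped back to its own
   territory, so cells can never overlap. Ground-truth areas are the exact
   shapely polygon areas, defined before and independently of rasterisation.
4. **Rendering.** Lumina near-white RGB (245, 243, 246) on a stained
   background RGB (168, 112, 160), additive Gaussian noise (SD 4 of 255).
   Rendering default is 1 µm/px; the geometry (and hence ground truth) is
   unchanged by the raster resolution.

**Quality grades.** `good` renders clean membranes only. `poor` adds the
stain-spillover artifact: for every cell, a membrane-adjacent band covering
`spillover_fraction` of the lumen (band depth solved by bisection on
negative polygon buffers) is blended toward a diluted-stain pink
(203, 171, 199), which sits on the stained side of the lumen/membrane colour
midpoint and is therefore read as tissue by the classifier — exactly the
failure mode of poor sections. `average` applies the artifact at half
strength to a quarter of the cells. The good/average/poor grading of real
slides is a visual judgement; the generator exposes continuous knobs
(fraction, noise, membrane thickness) rather than claiming a calibrated
"average" appearance.

**What the generator does not emulate:** nuclei, vessels, crown-like
structures, stain variation between batches, tissue folds and tears, and 3-D
sectioning effects (a section through a sphere under-represents the
equatorial diameter). Passing the recovery tests therefore demonstrates the
correctness of the pipeline machinery on well-stained material, not
robustness to every real-world artifact — on real slides, section quality
remains the dominant error source.

## Pixel classifier

A random forest (100 trees, √F features per split, unlimited depth, fixed
seed) over a multiscale filter bank: raw R, G, B plus Gaussian-smoothed
intensity, Gaussian-gradient magnitude and Laplacian-of-Gaussian per channel
at σ ∈ {1, 2, 4, 8} working pixels — 39 features. Classification runs at a
fixed *working resolution* (≥ the scan resolution; integer downsampling
factors use an exact block-mean). The default working pixel is 1.0 µm — a
20 µm² minimum object is then 20 px — while the large-area surveys in the
tests and the acceptance script run at 2.0 µm/px, which on the synthetic
material recovers counts exactly and mean areas within ~1% at a quarter of
the cost; this is the package's chosen analysis scale for survey-sized runs.

Training pools sparse scribble annotations (label 1 = fat, 2 = tissue) from
one or more calibrated images; both classes must be present, and a missing
class is reported by name. The model keeps its pooled training matrix so
annotations of misclassified regions can be appended and the forest refitted
(`retrain_classifier`), mirroring the interactive annotate–review–retrain
loop. Accuracy is reported as the forest's out-of-bag pixel accuracy. The
fat decision is a vote fraction ≥ 0.5; pixels outside an optional ROI polygon
are forced to tissue. Classification is a pure function of (model, image,
ROI).

The two classes are deliberately *lumen* versus *any stained tissue*:
training a classifier to single out membranes against other stained
structures does not generalise across stain variation, whereas
empty-versus-stained does.

## Object builder

The create-objects stage uses the validated settings: minimum object size
20 µm², minimum hole size 30 µm², split objects on.

* **Connectivity duality.** Fat components are 4-connected, background
  8-connected. This stops fat from leaking diagonally through one-pixel
  membrane gaps — the mechanism behind conjoined-cell misdetections.
* **Thresholds** are real-valued in µm² (`threshold_px = threshold_um2 /
  mpp²`, no rounding). An object is kept if area ≥ threshold (inclusive); a
  hole is filled if area < threshold (the parameter names the smallest kept
  hole). Background touching the mask border is never a hole. Both
  conventions are boundary-tested.
* **Splitting.** Marker-based watershed on the negated Euclidean distance
  transform. Markers are the regional maxima of the h-reconstruction of the
  EDT (h = 2 px): reconstruction-by-dilation of EDT − h under EDT, then
  plateau-aware regional maxima. This merges maxima whose separating saddle
  is shallower than h — including equal-height twin peaks a few pixels
  apart, which a residue-threshold h-maxima keeps apart no matter how large
  h is (discretised EDTs of convex lumina produce such twins routinely, and
  oversplit ≈6% of cells if used). Only necks deeper than 2 px split a
  component; splitting reassigns pixels and never deletes them, and
  fragments falling below the minimum object size after splitting are
  dropped. Components the watershed cannot seed keep their connected-component
  label. The splitting algorithm of the interactive tool this mirrors is
  undocumented; this choice is validated against ground truth, not against
  that tool.
* **Measurement.** Area = pixel count × mpp²; circular-equivalent diameter
  2·√(A/π); centroid and traced outer boundary (sub-pixel marching-squares
  contour) in µm slide coordinates. Objects export to GeoJSON
  FeatureCollections (µm coordinates) and flat CSV.

## Morphometry

Summaries mirror spreadsheet COUNTIFS/AVERAGEIFS aggregation: objects are
filtered to an inclusive area range (default 500–100 000 µm²), then count,
mean ± SD area, mean ± SD diameter and density are reported. The mean
diameter is the mean of per-cell diameters — strictly below the diameter of
the mean area for skewed size distributions (Jensen's inequality), a
distinction visible in real cohort tables. SDs are sample SDs (n−1),
matching standard statistical-package descriptives. Density divides the
count by the annotated ROI polygon area (default) or, behind an explicit
flag, by the convex hull of detected centroids; the drawn-region convention
is the default because the workflow annotates the region of interest before
detection. Empty summaries report NaN means (and NaN SDs at n = 1) and
density 0.

## Agreement statistics

For paired per-sample measurements from two methods (n subjects × k = 2):

* **ICC(C,1)** — two-way mixed-effects, consistency, single measures:
  ICC = (MSR − MSE)/(MSR + (k−1)·MSE) from the subjects × methods ANOVA.
  95% CI from F = MSR/MSE with df (n−1) and (n−1)(k−1):
  lower = (F/F₁₋α/₂ − 1)/(F/F₁₋α/₂ + k − 1), upper with the reciprocal
  quantile; the F test is the upper-tail test of ICC = 0 and the p-value is
  reported at full precision. Consistency ICC is invariant to a constant
  offset between methods and symmetric in the columns. ICC(A,1) (absolute
  agreement, McGraw–Wong CI) is available behind a flag. All-identical data
  raise an explicit degenerate-result error. Reliability labels follow the
  lower CI bound: ≥0.90 excellent, ≥0.75 good, ≥0.50 moderate, else poor.
* **Bland–Altman** — d = A − B; mean difference, sample SD, limits of
  agreement mean ± 1.96·SD, and the per-subject (mean, difference) table
  for plotting. The sign convention (first method minus second) is fixed
  and documented.
* **Paired regression** — OLS of B on A with Pearson r; a zero-variance
  predictor is an error.

Rows with missing values are dropped listwise at CSV load with a note. The
implementation is validated to 1e-10 against a loop-based sums-of-squares
oracle and cross-checked against pingouin's ICC(C,1) in the tests.

## Tiled large-area analysis

Interactive analysis of regions beyond ~20×10⁶ µm² is impractical in one
piece, and a full-slide feature stack would not fit in memory, so large ROIs
are processed on a grid: tile *cores* (default 2000 µm — the validated
survey-field side) partition the ROI bounding box, and each tile is read and
classified with a surrounding *halo* (default 200 µm, ≈ 2.7× the mean cell
diameter, chosen so cells crossing a core boundary — including the upper
tail of the size distribution — are seen whole by every adjacent tile; a
halo below half the expected maximum diameter triggers a warning). All tile
bounds snap to the working pixel grid so tile rasters align globally.

Objects whose bounding box lies inside a core are kept directly. Objects
touching a core boundary are re-assembled by unioning their pixel sets
across tiles in global pixel coordinates (union–find keyed on shared
pixels), so each cell is counted exactly once regardless of tile order; a
merged object spanning more than the halo is reported in a warning since its
union may be incomplete. Peak memory is bounded by the tile window, never
the ROI. On the synthetic material a 7.1×10⁶ µm² region analysed whole and
as four tiles yields identical counts and total areas, and a 60×10⁶ µm²,
~12,000-cell slide completes tile-by-tile from disk with the count matching
ground truth.

Feature filters use reflective padding at tile-window edges, so a pixel
within ~4σ (≤32 px) of a window edge can in principle receive slightly
different features than in an untiled run; the halo keeps such pixels away
from the kept objects, and the equivalence is verified rather than assumed.

Calibration: TIFF resolution tags (pixels per inch/cm) are the source of
truth; PNGs carry a JSON sidecar; an explicit µm-per-pixel override always
wins. Proprietary scanner containers are out of scope — convert to tiled
TIFF first.

## Reproducibility

Every stochastic component (point process, size jitter, noise, artifact
placement, scribble sampling, forest training) consumes an explicit seed
through independent child generators, so any run is bit-reproducible. CLI
runs write a `manifest.json` with the resolved parameters and SHA-256
digests of each output; rerunning with the same seed reproduces the digests
byte for byte.

## Validation problem sizes

The test-suite and acceptance-script runs use, as the package's chosen
validation conditions: 20 independent 2×10⁶ µm² regions at density 150
(≈300 cells each, ~6,000 cells total) for ground-truth recovery; a
7.1×10⁶ µm² region for tiled/untiled equivalence; one 60×10⁶ µm²,
≈11,700-cell slide for the whole-slide path; 200 random 64×64 masks for the
flood-fill oracle; and 100 seeded 50×2 matrices for the ICC oracle. Surveys
run at the 2 µm/px analysis scale.

## Known limitations

* The synthetic material is far cleaner than real H&E; real-slide accuracy
  is bounded by section and staining quality, and no single classifier
  generalises across strong stain variation — retraining per batch is the
  expected workflow.
* Splitting assumes roughly convex cells; genuinely interdigitated profiles
  may still be over- or under-split.
* Density uses the drawn ROI area; on sparse tissue the hull alternative
  can differ substantially, and neither convention is uniquely "correct".
* No interactive correction: misdetections are handled by retraining or by
  filtering the exported tables, not by manual deletion or redrawing.
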