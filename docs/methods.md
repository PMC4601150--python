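# Methods

This note documents the models, parameter choices and numerical
conventions behind `stenoquant`, and what the synthetic validation does
and does not establish about real angiographic data.

## Coordinate and intensity conventions

Arrays are indexed `(z, y, x)` with voxel spacing in mm per axis; all
distances, arc lengths and eligibility rules are computed in mm, never in
voxel counts, so anisotropic CTA-like (0.75 × 0.5 × 0.5 mm) and MRA-like
(2.0 × 0.7 × 0.7 mm) grids are handled uniformly.  Volumes are read and
written as NIfTI or MetaImage through nibabel/SimpleITK; seed points,
ROIs, centerlines and thresholds are JSON; all tables are CSV.

## Threshold estimation

The lower threshold is the fixed convex combination
`LT = (aorta + 2·background)/3`.  The aorta (contrast) value is the mean
of per-slice ROI *maxima* on the reference slice — the slice whose
aorta-ROI *mean* is greatest, ties to the smallest index — and the slices
10 mm proximal/distal; the ±10 mm offset is converted to slices by
rounding `10/slice-spacing` to the nearest integer and clamped at the
volume ends with a warning.  ROIs are circular discs in the axial plane.
Background is the mean of per-ROI means; the strict mode insists on 4
ROIs for CTA (psoas) and 3 for MRA (vertebral bodies), and a lenient flag
relaxes the count.  The CTA upper threshold repeats the three-slice
maximum recipe; it is deliberately a distinct operation because it exists
only for CTA and may use different ROI placements.

## Competing fuzzy connectedness

Membership is trapezoidal in intensity: 0 at or below LT, linear up to 1
at the contrast value, and 0 above UT when UT exists.  The affinity of a
voxel pair is the smaller membership, hence a path's strength is its
weakest voxel and the connectedness of a voxel to a seed set is the
maximum over 6-connected paths of that minimum (computed by a max–min
Dijkstra propagation per label).  The label rule is deterministic and
fully declared: greatest strength wins; ties are broken by the smaller
geodesic distance (mm, within the in-band region) to the label's seed
set, remaining ties by the lower label.  The geodesic tie-break matters
in noise-free interiors where memberships saturate at 1 and every label
reaches every voxel at full strength — there the rule reduces to a
Voronoi split along the lumen, which is what places the aorta/artery
boundary at the ostium.  The propagation is verified against exhaustive
Floyd–Warshall max–min closure (plus min-plus closure for the tie-break)
on random ≤ 6³ volumes; the comparison uses binary-exact spacings so path
length sums carry no rounding ambiguity.

## Centerline and segments

The labelled vessel is thinned to a 3-D skeleton (scikit-image), built
into a 26-connected graph with mm edge lengths, pruned of leaf spurs
shorter than 2 mm, and rooted by shortest path at the node nearest the
aorta attachment.  Node positions are smoothed per branch (moving
average, window 5, endpoints fixed) before tangents (central differences)
and arc lengths are computed; radii come from the Euclidean distance
transform with anisotropic sampling.  Thinning inevitably leaves short
side twigs near the ostium and at bulges; segment definition therefore
ignores junctions whose side branch continues less than 5 mm — the same
scale as the bifurcation exclusion margin — treating them as artifacts
rather than anatomical bifurcations.  Segment 1 runs from the root to the
first true bifurcation (or tip); segment 2 follows the largest branch,
defined as the largest mean distance-transform radius over the branch's
first 5 mm, to the next bifurcation or tip.  Manually drawn centerlines
(ordered points per branch, JSON) import into the same tree structure
with tangents recomputed, as a fallback for failed automatic extraction.

## Cross-section measurement

Planes perpendicular to the interpolated centerline tangent are resampled
trilinearly at a 0.2 mm in-plane pitch over a 12 mm field of view; the
in-plane axes are the tangent crossed with the most orthogonal world
axis, then orthonormalized, making the sampling deterministic.  The lumen
contour is the connected thresholded component around the centerline
point, regularized by hole filling plus morphological closing/opening
with a disc whose radius scales with the curvature parameter (scale 10 at
the default pitch gives a 2-pixel disc); pixels above UT are never lumen,
so adjacent calcifications are excluded.  Area is pixel count × pixel
area; the shortest diameter is the minimum Feret width over rotation
angles at a 1° step, evaluated on the convex hull with the pixel
footprint included.  MinD and MinA are minimized independently over all
positions; MaxD and MaxA are maximized independently over positions at
least 10 mm from the aorta and 5 mm from a bounding bifurcation, with an
unrestricted fallback (flagged) when no position qualifies — the
automated counterpart of reading the reference visually.  The arc-length
step defaults to 0.5 mm, about the finest voxel pitch.

Thresholding at LT, which lies below the half-maximum of the
lumen/background transition, dilates contours by a fraction of the local
voxel size.  Because the dilation is roughly constant in mm it inflates
small cross-sections relatively more than large ones and biases Dred
slightly downward; on the validation phantoms the worst case is about 5
Dred points at CTA spacing (a 50 % stenosis reads ≈ 45 %).  This bias is
a property of the measurement convention, not of the implementation.

## Phantoms

A phantom is an aorta cylinder (radius 8 mm, along z) plus tubular
arteries defined by smooth paths and radius profiles; stenoses are
raised-cosine dips with known centre, width and depth, so MinD/MaxD (and
circular areas) are available in closed form, including the eligibility
rules, before any voxelization.  The default single-artery phantom runs
~36 mm along +x in the axial mid-plane with baseline radius 2.5 mm,
lumen 300, background 60, one 8 mm-wide dip centred 22 mm from the
ostium, and (for CTA) an optional 800-intensity calcified blob.

Voxelization models partial-volume averaging: a voxel's value is
`background + (lumen − background) · f` with `f` the fraction of the
voxel footprint inside the lumen, estimated by 3³ supersampling of
boundary voxels against a union-of-balls representation of the tube (path
sampled every 0.05 mm).  Real CT/MR voxels average the signal over their
extent, and that averaging is precisely what makes sub-voxel measurement
possible at 2 mm slice spacing; a binary centre-inside rule remains
available (`voxelize="center"`).  Noise is additive Gaussian from a
seeded generator — scanner noise statistics are not emulated.  What
phantom tests show: geometric recovery of Dred/Ared through the full
pipeline under ideal contrast.  What they do not show: robustness to
motion, beam hardening, coil inhomogeneity, lumen irregularity or
eccentric plaque.

## Cohort simulation

The cohort generator emulates the study design around the pipeline:
~17 % of kidneys carry an accessory artery; first-segment true Dred is
drawn from a clipped normal (45 ± 25 points), second segments milder
(25 ± 15); baseline maximum diameters ~5.2 ± 0.7 mm.  Measurements add a
shared per-modality deviation (plus a small MRA bias) and independent
per-reader noise on the four absolute measures, with reductions derived
from the noisy values.  The functional reference is positive with
logistic probability in true severity (midpoint 60 Dred points, scale 6),
and ~13 % of kidneys receive an intermediate first-line result resolved
by a confirmatory test drawn from the same model.  Per-reader missingness
rates differ by modality and segment (second segments are harder), and a
small per-kidney rate makes a whole modality unmeasurable.  These
defaults are stated study conditions, not fitted quantities.

## Summarization and filtering

Reader merging averages the four absolute measures and recomputes
Dred/Ared from the averages, keeping MinD/MaxD/Dred internally
consistent; a percentage-averaging mode exists for sensitivity checks.
Ties in the per-kidney argmax over Dred break by larger Ared, then
segment 1 before 2, then lower artery id; the main artery is the one with
the largest merged MaxD, ties to the artery with more measurable
segments.  Cohort filtering drops, in order: kidneys of patients lacking
any investigation, kidneys non-measurable on either modality, and kidneys
contralateral to a positive kidney (including positives dropped as
non-measurable); solitary kidneys are never dropped by the contralateral
rule, and an accounting table records every step.

## Statistics

Limits of agreement use the literal mean ± 2·sample SD (denominator
n−1), not 1.96·SD.  The ICC is the two-way random-effects,
absolute-agreement, single-measures form computed from ANOVA mean
squares, with the F-based 95 % CI using Satterthwaite degrees of freedom;
the average-measures variant is available behind a flag, and the
implementation is cross-checked against an independent reference in the
tests.  AUC is the trapezoidal empirical area, identical to the
Mann–Whitney statistic with ties counted ½; orientation is declared per
measure (MinD/MinA inverted) so true signal yields AUC ≥ 0.5.  The
default AUC confidence interval and the paired AUC comparison use DeLong
placement-value covariances (Hanley–McNeil behind a flag).  No
multiple-testing correction is applied anywhere.

## Validation scale and limitations

The shipped checks run on one CPU in minutes: six full phantom pipelines
(two modalities × three stenosis depths), 50 exhaustive-oracle
segmentation volumes, 500 simulated kidneys for the approach ordering,
10⁵ differences for coverage and 500 replicates of n = 300 for the
DeLong null — sizes chosen to keep Monte-Carlo error well inside the
asserted tolerances.  Known limitations: clinical AUROC/ICC magnitudes
are not reproducible without patient data (the statistics are validated
on synthetic cohorts instead); stenosis length is deliberately not
measured; the level-set contour of the original interactive tool is
realized as threshold-plus-morphological smoothing at the contract level;
and the cross-section area uses the pixel-count convention rather than a
sub-pixel polygon.
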