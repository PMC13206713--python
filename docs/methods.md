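# Methods

This note documents the models, conventions and numerical choices behind
`choromap`, and what the synthetic-data tests do and do not demonstrate about
real OCT data.

## Choroid band and metrics

The choroid of each B-scan is the band between two real-valued boundary
curves supplied per A-scan: the RPE and the choroidoscleral junction (CSJ).
Curves are stored with sub-pixel precision; thickness is computed on the real
values, `CT = (csj − rpe) · axial_resolution`, while pixel counting uses a
single integer-row membership rule (`ceil(rpe) ≤ row < ceil(csj)`) shared by
the generator and the quantifier, so lumen/stroma pixel counts and the
ground-truth labels agree exactly. Per cell, `LA + SA` equals the cell's
choroid pixel count times the pixel area (A-scan spacing × axial resolution)
by construction — a conservation law asserted in the tests.

## Multiscale median-cut binarization

Within each column window of the band (default widths 32 and 64 columns plus
the whole region), the intensity sample is recursively split at its median
value into up to `n_levels` buckets (default 4, always a power of two).
Splits are at the median *value* with strictly-darker pixels on the dark side
and a `≤`/`>` fallback when the median equals the minimum; a constant segment
stays one bucket. The darkest half of the buckets is labelled lumen, and
labels from the different window widths are combined by strict majority
(options: any/all). Rationale for the dark-half rule: vessel lumen is
hypo-reflective, and taking half the buckets makes the label insensitive to
`n_levels`.

Two consequences matter for interpretation:

* On a noiseless two-valued band the value-based splits land exactly between
  the plateaus, so the lumen mask equals the ground truth pixel for pixel at
  any lumen fraction — the exactness oracle used throughout the tests.
* On continuous (noisy) intensities each median split is count-based, so the
  labelled lumen fraction of a window is pulled toward 0.5. When the two
  tissue modes are well separated and roughly balanced the threshold falls in
  the inter-mode gap and accuracy is limited only by the mode overlap (the
  seeded accuracy fixtures use lumen fraction 0.5 and noise SD 20 on a
  60/180 intensity split, giving pixel agreement ≳0.99); with strongly
  unbalanced phases the estimate is biased toward 0.5. This count-bias is
  intrinsic to median-cut labelling with a fixed dark-bucket share and is the
  main caveat when reading absolute CVI values from noisy data; difference
  maps between groups processed identically are affected far less.

A constant-intensity band is labelled all-stroma with a warning (documented
convention); a band of zero height at every column is an error.

## Vessel-shadow exclusion

Retinal-vessel shadows attenuate everything beneath the vessel. For each
A-scan the mean intensity below the RPE (to the scan bottom) is compared
across the B-scan: columns below `median − 2·MAD` (MAD scaled by 1.4826 to be
sigma-consistent) are shadow candidates. Because a column crossing a large
choroidal vessel is also dark below the RPE, a candidate is confirmed only if
the retinal band immediately above the RPE — which a genuine overlying shadow
must darken too, and choroidal anatomy cannot — is below the same robust cut
of its own distribution. Confirmed columns are dilated by one column per
side and excluded from all aggregation (their cells become invalid, never
zero). On clean noiseless scans this confirms nothing (the retinal means are
constant), and on the seeded noisy fixtures it detects every true shadow
column with ~1% false positives.

## Grid mapping and aggregation

The 60 × 60 grid covers 7200 × 7200 µm centred on the fovea; indices are
`floor((coord + 3600)/120)` with half-open cells (rows follow x along the
B-scan, columns follow y across B-scans). The standard cube places 61 B-scans
at 120 µm spacing spanning exactly the grid, so the last scan lies on the
closed upper edge; it is assigned to the last cell row band rather than
discarded. Per cell, CT is the median of valid column CTs (medians are the
reporting convention throughout), LA/SA are pooled pixel counts scaled to
µm² (areas add), and CVI is computed from the pooled pixels rather than by
averaging per-column ratios. A cell is valid iff at least 50% of its
geometrically expected samples are valid — enough to survive moderate
shadowing without taking medians of near-empty cells.

## Spatial templates

ETDRS rings are half-open annuli at radii 500/1500/3000 µm with a
near-periphery ring beyond, quadrants split at the 45° diagonals (boundary
points assigned to the clockwise-following quadrant), and nasal/temporal
mirrored for left eyes so labels are anatomic; 13 sectors are realizable.
Cell membership everywhere is by cell centre, keeping counts integral; the
price is a small discretization error against continuous areas (the 1-mm
disc holds 52 cells vs a continuous-area 54.5). Eccentricity bins are
half-open 0.05-mm annuli; the bin centre `(i + 0.5)·0.05` mm is the
regression abscissa.

## Group differences and statistics

Difference maps take, per cell, the median over eyes within each group
(cells valid in at least half the eyes of both groups) and apply the
symmetric percent change `100·(x − c)/((x + c)/2)`; the raw form
`100·(x − c)/x` is available but unbounded near zero denominators, which is
precisely why the symmetric form is the default. Non-positive denominators
invalidate the cell instead of producing infinities.

Global comparisons use the Wilcoxon signed-rank test on per-eye whole-grid
medians with eyes paired by index (exact null for n ≤ 25, zero differences
dropped, all-zero differences reported as p = 1); unmatched groups fall back
to the rank-sum test with a warning. Sector analysis runs a Kruskal–Wallis
test across the four rings on cell values and per-sector one-sample Wilcoxon
tests against zero, Holm-corrected across the 13 sectors; sectors with fewer
than 5 valid cells are excluded and flagged. Shapiro–Wilk is provided to
justify the nonparametric reporting and never switches tests silently.

Eccentricity models are ordinary least squares of degree 1 and 2 on the
per-bin medians over the default range 0–3 mm with bins equally weighted
(cell-count weighting is a config option). Since the quadratic never has a
lower R² than the nested linear model, the quadratic is chosen only when its
R² gain exceeds 0.01; a constant response is reported as a flat linear fit
with R² defined as 0. Model features — the linear x-intercept `−k/m`, the
quadratic vertex `−b/(2a)` with its extremal value, and real roots inside the
fit range — are kept at full precision and rounded to 0.1 mm only in the
reporting layer. Metric–metric association uses Spearman correlation on
per-bin medians by default (matching how eccentricity data are presented) or
on shared cells.

## Synthetic data: what it emulates, and what it does not

The B-scan generator renders a flat retina block, an RPE at a configurable
(possibly spatially varying) depth, a choroid band of bright stroma
(default 180) with dark elliptical lumina (default 60), sclera beneath,
vertical shadow bands (multiplicative attenuation below the retinal
surface), and additive Gaussian noise clipped to [0, 255]. Geometry follows
the emulated protocol: 61 B-scans, 8.6 mm scan length, 1.8 mm depth,
3.9 µm axial resolution, 768 A-scans per B-scan; the fovea sits at the
volume centre (a real-data fovea offset is a metadata field).

Vessels are placed by rejection sampling with overlap allowed, *stratified
per grid-column block* (one 120 µm cell width, clipped at block borders):
each block accepts random ellipses until its realized lumen areal fraction is
within ±0.01 of the target, rejecting and shrinking proposals that overshoot.
Fraction — not vessel count — is the quantity CVI measures, and controlling
it at the cell scale makes every grid cell a calibrated oracle. Unreachable
targets (vessels much larger than the tolerance window and the band) raise
an explicit error after a bounded number of attempts. Default vessel
semi-axes are 20–80 µm, i.e. small-to-medium choroidal vessels; the default
lumen fraction is 0.5 so that binarization accuracy under noise reflects
mode separability rather than the median-cut count bias described above,
with the fraction swept explicitly in the monotonicity tests.

The grid-level cohort generator works directly on per-cell metrics: control
eyes are a smooth positive baseline (CT ≈ 300 µm declining gently with
eccentricity, CVI ≈ 0.65 slightly elevated foveally, LA/SA consistent with
both) times multiplicative log-normal eye-level and independent cell-level
effects (keeping every denominator of the percent-change formula positive);
case eyes additionally scale each cell by `(200 + p)/(200 − p)` so that the
true symmetric percent change between group medians equals the prescribed
profile `p(r)`. The profile is evaluated at the cell's eccentricity-*bin
centre* — the same abscissa the regression uses — so a noiseless embedding
round-trips through the full pipeline with R² = 1 and coefficient error at
machine precision.

Not emulated: anatomically realistic retinal layers, drusen or reticular
pseudodrusen lesions, speckle's multiplicative statistics, continuous vessels
across block borders, and any within-group *spatial* covariance of metrics
beyond the smooth baseline (cell noise is independent). Passing tests
therefore demonstrate the correctness of the measurement and statistical
machinery under known truth, not the clinical effect sizes of real cohorts.

## Calibration and recovery conditions

Parameter recovery is verified by embedding a quadratic CVI profile
(4, −20, 16) into 40-vs-40-eye cohorts with 3% between-eye and 2% cell-level
variation: across 20 seeded replicates the quadratic is chosen every time and
every coefficient lands within ±15% of truth. Null calibration uses 100
seeded zero-effect replicates of 20-vs-20 cohorts: the paired global Wilcoxon
rejects at the 5% level in ≤10% of replicates. The sector-level null is run
with cell-level noise only: a between-eye random effect shifts the entire
group-median map by a common offset, which per-sector one-sample tests on
cells cannot distinguish from a true effect (pseudoreplication). That is a
real limitation of cell-level sector testing, not of the simulation — at the
sector level the tests are calibrated against within-map noise, and eye-level
inference is what the global paired test is for.

Problem sizes throughout (full 61 × 462 × 768 cubes for image-level checks,
grid-level cohorts for statistical checks, 20–100 replicates) were chosen so
the whole suite verifies every stage against ground truth while remaining
quick to run on a single CPU.
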