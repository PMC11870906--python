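# Methods

This note documents the models, conventions and numerical choices behind
`tumorshape`, and what the synthetic-data experiments do and do not show
about real imaging data.

## Shape descriptors

A lesion is a single closed simple polygon in physical millimetres
(counter-clockwise after ingestion; self-intersection is an error, validated
with Shapely). All geometry is exact polygonal geometry:

- area: absolute shoelace sum;
- perimeter: sum of Euclidean edge lengths including the closing edge;
- convex hull: Andrew's monotone chain with strict turns, so collinear
  boundary points are dropped and `hull(hull(P)) = hull(P)` exactly;
  lexicographic (x, then y) ordering breaks sort ties;
- maximum Feret diameter: exhaustive maximum pairwise distance over hull
  vertices (hulls of lesion outlines are small; rotating calipers would gain
  nothing measurable);
- solidity = area / hull area, clamped to 1.0 against float rounding only
  (it is mathematically ≤ 1);
- circularity = 4π·area / perimeter², capped at 1.0 with a logged warning;
  the raw value is kept in `circularity_raw`.

**Perimeter convention.** Clinical analyses of this kind are often run in
general-purpose image tools whose chain-code perimeter estimators differ
from polygonal perimeters, and which may or may not cap circularity.
`tumorshape` uses the polygonal (sub-pixel) perimeter because it satisfies
the isoperimetric bound 4π·A ≤ P² exactly for every simple polygon — this is
asserted as a property test. Absolute circularity values from other tools
may therefore differ slightly; solidity is unaffected.

**Masks.** Binary masks enter through marching squares at iso-level 0.5
(pixel-centre coordinates, zero-padded, largest connected component with a
warning if there are several). The raw marching-squares boundary is a
staircase whose length overestimates the true perimeter by a few percent *at
any resolution*, so the ring is smoothed with a circular moving average over
5 boundary vertices before measurement. The window is in pixel units, so the
induced rounding of genuine corners vanishes as resolution grows; a
rasterized disk of radius 50 px measures circularity ≈ 0.993 and a ~500 px
disk reproduces area, perimeter and Feret diameter within 1%. Degenerate
limit: a single-pixel mask yields the inscribed diamond of area 0.5 mm²
under this convention (the pixel-count value, 1 mm², is an upper bound).

## Longitudinal assembly and response labels

Timepoints are baseline, 3 months ("m3") and 6 months ("m6"). Shape
variation is *baseline minus follow-up*; the sign convention is labelled in
every output ("positive = index decreased", i.e. the tumor became more
irregular/less circular). Missing endpoints make the variation absent, never
zero.

RECIST 1.1 is deliberately simplified to one target lesion: CR at diameter
0; PR at ≥ 30% shrinkage from baseline; PD at ≥ 20% growth from the nadir
(running minimum over available timepoints, baseline included) *and* ≥ 5 mm
absolute growth; SD otherwise, with precedence PD > PR > SD on boundaries.
Sum-of-diameters bookkeeping, non-target assessment and new-lesion rules are
out of scope. When an explicit 6-month label is supplied it overrides the
diameter-derived one. The exclusion cascade (no target separate from
locoregionally treated lesions, then no follow-up imaging) is applied in
that fixed order, and counts are conserved for the study flowchart.

## Survival statistics

All estimators take `(time in days > 0, event observed)` records.

- **Kaplan–Meier**: product-limit estimate; censorings tied with events at
  the same time remain at risk for those events. Median = smallest t with
  S(t) ≤ 0.5 (NaN when the curve never reaches 0.5). Confidence intervals
  use the log(−log S) transform with Greenwood variance; the median CI is
  read off the band (open ends reported as NaN). This CI choice follows the
  common Brookmeyer–Crowley-style convention; other software may differ.
- **Log-rank**: two-group, hypergeometric variance under ties, χ² with 1 df.
- **Kendall τ_b** with tie corrections; p by normal approximation with the
  tie-corrected variance of C − D, or exact permutation enumeration for
  n ≤ 8. RECIST status enters as the ordinal CR < PR < SD < PD.
- **Friedman test** with average ranks and the standard tie correction;
  incomplete rows (patients missing a timepoint) are dropped with a warning.
- **Cohen's κ** with marginal-product expected agreement; undefined (NaN,
  warned) when both raters are constant and identical.

These are implemented directly on numpy arrays and are cross-checked in the
test suite against lifelines (KM, log-rank), scipy.stats (Friedman, Kendall)
and scikit-learn (κ) to 1e-6 on randomized datasets.

### Maximally selected rank statistics

Candidate cutpoints are midpoints between consecutive distinct sorted index
values whose induced split keeps at least `min_prop` (default 0.1, a common
convention; configurable) of the subjects on each side. For each candidate
the standardized log-rank statistic |Z| is computed; the argmax is selected,
ties resolved toward the smaller cutpoint. The scan is vectorised: records
are sorted by time once, per-(time-block, value-rank) histograms give the
low-group at-risk counts by a suffix cumsum over blocks and a cumsum over
ranks, so a batch of permutations costs O(B·m·R) numpy passes.

The primary p-value is a **permutation p** of max|Z| with the index values
permuted against the survival records, using the add-one estimator
(1 + #{perm ≥ obs}) / (1 + B) with a fixed seed — valid by construction and
reproducible bit-for-bit. Two further numbers are always reported, labelled:
the naive χ² p of the log-rank at the selected cutpoint (ignores selection,
anti-conservative) and the Miller–Siegmund asymptotic approximation for the
supremum of a standardized Brownian bridge over the admissible quantile
band. Degenerate variance at a candidate yields Z = 0 there; no admissible
candidate raises an error.

`ShapeSurvivalModel` wraps this as model/results objects: `fit()` returns
the selected cutpoint, all three p-values, the per-group Kaplan–Meier
curves with medians and a text `summary()`. `analyze_cohort` runs the whole
battery over the configured indices and adds an optional Holm adjustment
across indices (unadjusted values are always kept; multiplicity across the
several indices tested is otherwise left to the reader, clearly labelled).

## Synthetic cohorts

The generator emulates the statistical structure of the study cohort, not
its images:

- **Contours**: star-convex radial perturbations
  r(θ) = R(1 + Σ aₖ·cos(kθ + φₖ)) on a uniform grid of ≥ 64 vertices;
  Σ aₖ < 1 keeps the radius positive and the polygon simple. Solidity
  decreases monotonically in a single mode's amplitude, so
  `calibrate_amplitude` can bisect to any achievable target solidity
  (tolerance 1e-3); a coarse amplitude–solidity table per (k, n_vertices)
  seeds the bracket. Written contour files, re-measured through the full
  I/O + geometry path, reproduce the latent solidity within 2e-3.
- **Cohort defaults** mirror the intended study conditions: 37 patients;
  baseline solidity ~ N(0.95, 0.025) truncated to the achievable range
  (centre and spread chosen to match the reported cohort median/IQR);
  zero-mean drift with sd 0.015 at 3 months and 0.035 at 6 months (spread
  widens over time, medians stay flat); missing-scan fractions 6/37 (3 mo)
  and 4/37 (6 mo), missing completely at random; lobe count k ∈ {3..7} and
  phase random per contour; base radius uniform on 10–35 mm.
- **Survival**: exponential with hazard h₀·exp(β·z); by default
  z = 1{6-month solidity < 0.956} (the dichotomised-shape scenario) with
  h₀ = ln2/525 per day (favourable-group median 525 days) and β = ln 2.5; a
  linear-in-solidity-variation covariate is the alternative. Censoring is an
  administrative horizon (default 3 years) plus a uniform-dropout fraction
  (default 15%); the analytic event probability under this model is stored
  per patient in the truth file and checked against the empirical event
  fraction. PFS is generated on a doubled hazard with the same shape effect,
  for schema completeness.
- **Determinism**: byte-identical outputs given the config; shape
  realisation draws live on a separate child stream so the clinical table is
  identical with or without contour generation. Exponential survival was
  chosen for the analytic tractability of these checks; a Weibull extension
  would only change the `truth` bookkeeping.

**What passing tests show — and don't.** The synthetic shapes are
star-convex with a single harmonic mode: real lesions have multi-scale
irregularity, segmentation noise and observer variability, none of which is
modelled. Recovery of a step-hazard cutpoint on synthetic cohorts
demonstrates the correctness and calibration of the *pipeline*, not the
clinical effect size; cohort-level values from the motivating study (median
indices, the 0.956 threshold, median survivals) derive from non-public
patient images and are not reproduced here.

## Problem sizes and test design

The acceptance-style checks run at sizes chosen to make the Monte-Carlo
answer stable while staying desk-scale: 500 null simulations at n = 60 with
399 permutations each for the calibration of the permutation p (expected
rejection 5%, binomial SE ≈ 1%), and 100 end-to-end replicates at n = 300
with 199 permutations each for cutpoint recovery (p ≤ 0.05 is decidable at
B = 199). The permutation count only affects Monte-Carlo resolution, not
validity, because the add-one estimator is exact at any B.

## Known limitations

- Single-lesion RECIST only; no iRECIST confirmation logic or new-lesion
  detection.
- 2D only: no volume or sphericity; no DICOM ingestion (contour CSV, PNG or
  NIfTI slice instead); no automatic segmentation.
- The OS/PFS time origin is taken from the clinical table as given.
- Whether "size variation" means diameter or area change is ambiguous in
  this field; both are computed and labelled (`size_variation_mm`,
  `area_variation_mm2`).
- Circularity values are comparable across tools only if the perimeter
  estimator and capping convention match (see above).
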