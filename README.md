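# tumorshape

Quantitative 2D tumor morphology and shape-based survival analysis for
longitudinal lesion imaging.

Size-based response criteria (RECIST 1.1) can miss the atypical evolution of
tumors under immunotherapy, especially when lesions have also been treated
locoregionally (ablation, chemoembolization). `tumorshape` implements the
complementary *shape* track of that analysis: a target lesion is manually
segmented on the axial slice of maximum diameter at baseline, 3-month and
6-month follow-up, and two dimensionless descriptors are computed per
timepoint,

- **solidity** = Area / Area(convex hull) — 1.0 for convex outlines, lower
  when the border has protuberances or depressions;
- **circularity** = 4π·Area / Perimeter² — 1.0 for a perfect circle,
  approaching 0 for elongated or irregular shapes.

**Shape variation** is defined as the index at baseline minus the index at
6-month follow-up, so a positive value means the tumor became more irregular
(solidity) or less circular (circularity) under treatment.

The survival question — does the shape index stratify overall survival? — is
answered with **maximally selected rank statistics**: every admissible
cutpoint c of the index is scanned, the standardized two-group log-rank
statistic |Z(c)| of the split {index ≤ c} vs {index > c} is computed, and
the cutpoint maximising |Z| is selected. Because the cutpoint is chosen to
maximise the statistic, naive log-rank inference at the selected cutpoint is
anti-conservative; the package reports a seeded permutation p-value of
max|Z| (index values permuted against the survival records) as the primary,
selection-corrected inference, plus the Miller–Siegmund asymptotic band
approximation as a cross-check. Kaplan–Meier curves with log-log confidence
intervals, the log-rank test, Kendall's τ_b (shape vs ordinal RECIST
status), the Friedman test (shape over timepoints) and Cohen's κ
(inter-reader agreement) round out the toolkit. Because patient images are
not public, a synthetic-cohort generator produces star-convex lesion
contours r(θ) = R(1 + a·cos(kθ + φ)) with amplitude calibrated to any
target solidity, and exponential survival whose hazard h₀·exp(β·z) is tied
to 6-month shape — so every stage is testable against known ground truth.

## Worked example

```python
import numpy as np
import tumorshape as ts
from tumorshape.pipeline import cohort_from_files

# a synthetic cohort: 120 patients, hazard ratio 2.5 for 6-month solidity < 0.90
cfg = ts.SyntheticCohortConfig(
    n_patients=120, c_true=0.90, beta=np.log(2.5),
    baseline_solidity_mean=0.90, baseline_solidity_sd=0.05,
    censor_horizon_days=730.0, h0=np.log(2) / 500.0, seed=7)
sim = ts.simulate_cohort(cfg, out_dir="cohort_files")

# contour files -> shape features -> analysis-ready table -> stratification
cohort = cohort_from_files("cohort_files/lesions.csv", "cohort_files/clinical.csv")
res = ts.ShapeSurvivalModel(cohort, index="solidity_m6").fit(n_perm=1999, seed=1)
print(res.summary())
```

```
Shape-index survival stratification (maximally selected rank statistics)
==========================================================================
index: solidity_m6                  n = 104 (16 rows dropped: missing data)
survival: os_days / os_event; admissible band: min_prop = 0.1
--------------------------------------------------------------------------
selected cutpoint            0.9003   (of 83 candidates)
max |standardized logrank|    4.629
p (permutation, B=1999)    0.0010   <- selection-corrected
p (naive logrank at cut)     0.0000   <- ignores selection
p (asymptotic band approx)   0.0002
--------------------------------------------------------------------------
low  group (index <= cut): n = 51   median OS 188 d (95% CI 130-258)
high group (index >  cut): n = 53   median OS 642 d (95% CI 409-704)
log-rank at cutpoint: chi2 = 21.429, p = 0.0000
==========================================================================
```

The selected cutpoint 0.9003 recovers the simulated truth (0.90): patients
whose 6-month solidity lies at or below it have a median overall survival of
188 days versus 642 days above it, and the permutation p-value 0.001 says
the stratification survives correction for having searched 83 candidate
cutpoints. Single-contour descriptors are just as direct:

```python
square = ts.Contour([(0, 0), (1, 0), (1, 1), (0, 1)])
ts.shape_features(square)
# ShapeFeatures(area=1.0, perimeter=4.0, hull_area=1.0, solidity=1.0,
#               circularity=0.7853981633974483, max_diameter=1.4142135623730951)
ts.shape_variation(0.95, 0.82)   # 0.13  (positive = less solid at 6 months)
```

A command line mirrors the library: `tumorshape simulate | features |
cohort | analyze` (see `tumorshape --help`).

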