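# Methods

## Scope and model

`trtrel` quantifies test–retest reliability of white-matter bundle
reconstructions from two scan sessions of the same subjects.  It begins
where tractography ends: inputs are per subject × session × bundle
streamline sets (TRK/TCK), optional streamline density maps (NIfTI-1), a
per-subject affine registering session-1 space to session-2 space, and a
long-form CSV of per-bundle scalar measures.  Everything upstream —
denoising, motion correction, fODF estimation, tracking, bundle
segmentation, registration *estimation*, scalar-map computation — is out of
scope and treated as given.

All geometry lives in world RAS millimetres; TRK's voxel-mm corner-origin
convention and TCK's scanner space are converted on load by the nibabel
format handlers.  A world point belongs to the voxel whose index is the
floor of its inverse-affine image (half-open cells), an unambiguous and
testable convention.  Two affines are considered equal when their maximum
absolute elementwise difference is ≤ 1e-4, which absorbs text-file
round-off.

## Streamline density maps

The weight of a voxel is the number of *distinct* streamlines whose path
intersects it; one streamline contributes at most 1 per voxel however often
it re-enters.  Visitation is computed exactly: each polyline segment is
clipped against the integer index planes it crosses, and the voxel of every
inter-crossing interval is read off at the interval midpoint.  An earlier
design resampled each streamline at 0.2 × the smallest voxel edge before
voxel assignment; that approximation systematically misses voxels a path
clips only briefly (in random-polyline trials it lost a couple of support
voxels per bundle), so the exact traversal replaced it.  The tests compare
against an independent brute-force oracle that supersamples at 0.01 mm;
agreement is exact except for voxels whose true intersection length is
below the oracle's own step, which a finite sampler cannot resolve (the
test verifies each such voxel's clip length explicitly).

Bundle volume is (number of voxels with weight > 0) × voxel volume, with
the support threshold configurable.  Mean streamline length is the
arithmetic mean of per-streamline arc lengths.  Along-tract scalar
aggregation defaults to the density-weighted mean Σ W·s / Σ W — consistent
with the weighting rationale of the weighted Dice — with a plain mask mean
available; which of the two a given study used is rarely stated, so both
are exposed.

## Weighted Dice

For density maps W_i, W_j on a common grid,

    D = (Σ_{v'} W_i,v' + Σ_{v'} W_j,v') / (Σ_v W_i,v + Σ_v W_j,v),

where v' are voxels with strictly positive weight in *both* maps.  D is
symmetric, scale-invariant in the weights, equals 1 exactly when the two
supports coincide, and reduces to the set-arithmetic Dice coefficient on
binary maps.  The acceptability threshold defaults to 0.70 and the
comparison is ≥ (0.70 itself passes).  No registration is performed here:
callers transform session-1 bundles with the supplied affine first, then
rasterize both sessions onto the session-2 grid — the pipeline mirrors that
order, and rasterizes on the session-2 density map's grid when one exists,
else on a padded bounding-box grid at 1 mm (configurable).  The report
records per-bundle mean, median and range across subjects, since which
summary a given study reports is often unstated.

## ICC(A,1)

For an n × k table of subjects × sessions (k = 2 here), the two-way
crossed decomposition gives SSR, SSC, SSE (clamped at zero against
round-off; components below 1e-12 of the total sum of squares are snapped
to exact zero so degenerate tables are recognized) and mean squares
MSR = SSR/(n−1), MSC = SSC/(k−1), MSE = SSE/((n−1)(k−1)).  The estimate is

    ICC = (MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE)).

The 95% CI uses the F-distribution construction with a Satterthwaite
approximation for the denominator degrees of freedom — the interval SPSS
prints for "two-way, absolute agreement, single measures".  Significance
against ICC = 0 is the one-sided F = MSR/MSE test on (n−1, (n−1)(k−1))
degrees of freedom, the test statistical packages report alongside the ICC.
Categories use half-open bins — excellent ≥ 0.75, good [0.60, 0.75), fair
[0.40, 0.60), poor < 0.40 — closing the gap the conventional verbal labels
leave between 0.74 and 0.75.  Negative estimates are reported as computed
(category poor), preserving estimator properties for simulation studies.
Subjects missing either session are dropped per table (pairwise-complete),
so a bundle absent in one subject is analyzed with n−1 subjects.

## Bland–Altman

Differences are session 1 − session 2 (configurable sign).  Limits of
agreement are mean ± 2 SD of the differences (sample SD, n−1; the
multiplier is configurable and defaults to 2 rather than 1.96).  Limits of
agreement describe the spread of individual differences; they are not a
confidence interval of the mean difference, and the result object labels
them accordingly.  `good_agreement` is true when ≥ 95% of subjects fall
inside the limits; because small cohorts make attainable fractions coarse
(with n = 18 the strictest non-unity fraction is 17/18 ≈ 94.4%), the
integer count outside the limits is reported alongside.

## Synthetic cohort

Scalar tables follow y_ij = μ + b_i + s_j + e_ij with independent normal
subject, session and residual effects.  Drawing the session effect randomly
(rather than fixing it) makes the population absolute-agreement ICC exactly
σ_b²/(σ_b² + σ_s² + σ_e²), giving parameter-recovery tests an exact target.
Default per-metric scales (FA mean 0.45, MD 0.8 μm²/ms, volume 9000 mm³,
MLS 100 mm, …) are plausible tractometry magnitudes chosen once as
configuration values — no per-bundle means are available to calibrate to —
with variance ratios in the good-to-excellent range.

Bundles are tubes: 30 jittered copies (SD 1 mm, smooth constant-plus-linear
per-streamline offset) of a cubic-spline centerline per bundle, mirrored
across hemispheres, on a 32 mm isotropic 1 mm grid; the session-2
centerline is displaced by 0.6 mm by default, which yields mean wDSC values
in the high-0.7s.  The default cohort is 18 subjects × 2 sessions × 8
bundles × 7 metrics with one subject's right uncinate absent in both
sessions, so the pipeline's pairwise-complete handling (n = 17 for that
bundle) is exercised end to end.  Sub-seeds derive from the master seed via
spawn keys indexed by (kind, subject, bundle) — generation order cannot
change the data.

What the generator does *not* emulate: real anatomy, scanner noise, motion,
partial-volume effects, tracking failure modes, or any correlation between
a bundle's geometry and its scalar metrics (metrics are simulated
independently of the tubes).  Passing tests therefore demonstrate that the
statistics and geometry are computed correctly and that the estimators
recover known truth — not that any particular acquisition protocol is
reliable.

## Numerical choices and problem sizes

Monte-Carlo checks run at the study size (n = 18, k = 2): 500 replicates
per true-ICC level for recovery and CI coverage, 2000 tables for the size
of the F test, 100 replicate cohorts per reliability regime for the
category-separation check, and a 10,000-pair draw for the ±2 SD normal
coverage of the Bland–Altman limits.  Density-map tests use 15³–32³ grids.
These sizes keep the full suite to a couple of minutes on one core while
leaving the Monte-Carlo bands far wider than the observed deviations.

Known limitations: no along-tract profiles (one mean per tract only), no
surface-distance bundle metrics, no multiple-testing correction across the
56 ICC tests (deliberately — the analysis this mirrors applies none), and
the wDSC is computed on whatever grid the inputs supply; the report records
the voxel size rather than enforcing one.
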