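# Methods

## Measurement model

All coordinates are physical: depth in µm from the image top, lateral
position as signed eccentricity in µm with nasal positive (left-eye scans
are mirrored on read). Scans are analyzed at a common scale of 2.27 µm/px
axially and 5.26 µm/px laterally; the lateral scale of a native scan is
`nominal_length_mm · (axial_length_mm / 24 mm) · 1000 / n_ascans` µm/px,
rescaling is bicubic (scipy zoom, edge-clamped), and registered frames are
averaged pixelwise (at most 19; extras are dropped with a warning).

**Outer segments.** OS length at a lateral position is the depth distance
between the EZ and IZ reflectivity peaks of a 5-px-wide longitudinal
reflectivity profile (LRP). Peaks are strict local maxima inside ±25 µm
windows around the segmentation-provided EZ/IZ depths — windows are clamped
midway toward the neighboring ELM and RPE bands so those brighter bands
cannot capture the search — and are refined by 3-point parabolic
interpolation. A monotone intensity transform does not move an argmax, so
peak positions are detected on stored intensities without display
linearization. The apparent OS maximum is seeded deterministically by a
coarse argmax scan every 100 µm (ties toward the scan center), OS length is
sampled every 25 µm within ±250 µm of the seed (21 samples), and a
single-term Gaussian `L(x) = a·exp(−((x−b)/c)²)` is least-squares fit
(initialization: a = max sample, b = argmax, c = half span; tolerances
1e-10). `a` is the maximum OS length and `b` the foveal location. Flat or
non-converging sample sets fall back to the raw maximum (`fallback_flat`).
The OS ratio divides `a` by the mean of single-LRP OS lengths at ±1.75 mm;
if only one side is measurable the ratio uses that side (`os_one_sided`).

**Foveal location.** The Gaussian-fit center is the primary foveal
definition, but it is meaningless when OS elongation is absent: with a
peak-to-trough relief of the 21 OS samples below 2 µm (≈ the jitter of
peak detection at 1% image noise) the fitted center is noise-driven. The
pipeline then falls back, in order, to the ONL foveal rule (below), the
minimum of the smoothed IRL profile, and finally the scan center, each
flagged. This mirrors how foveal frames are identified in practice from
whichever specialization is present. The 2-µm threshold is the package's
own choice; it only matters for eyes whose OS ratio is within a few percent
of 1.

**Inner retinal layers.** IRL thickness is INL/OPL depth − ILM depth,
smoothed by a centered 30-px moving average (window truncates at scan
edges; ≈158 µm at the common scale), linearly interpolated on a 100-µm grid
centered on the fovea. The IRL ratio is the mean of the ±1 mm values over
the foveal (grid-zero, smoothed) value. The smoothing window slightly fills
a narrow pit; with the synthetic pit width of 500 µm the induced bias on
the IRL ratio stays under ~1.5% at the deepest pits.

**Outer nuclear layer.** ONL thickness is ELM depth − HFL-outer depth
(HFL excluded, as in directional-OCT-based segmentation), interpolated
every 50 µm within ±2 mm of the ONL fovea — the location maximizing the
ONL-to-IZ distance, ties toward the scan center. Of the two candidate ONL
boundaries the inner (HFL-outer) one is used in that rule; this is
configurable in principle but fixed here. The ONL ratio is the grid-zero
value over the mean of the ±1.75 mm values.

## Grading

Grades follow a decision tree over presence calls: pit present (IRL ratio ≥
pit cutoff) → grade 1, split into 1a/1b by a deep-pit sub-cutoff; else OS
elongation present → 2; else ONL thickening present → 3; else 4. The scale
defines the 1a/1b split subjectively, so the sub-cutoff is a free
parameter defaulting to 2.0 (midpoint between the pit cutoff and a fully
specialized synthetic IRL ratio). Presence cutoffs are calibrated by ROC
against reference grades: thresholds sweep the midpoints of sorted unique
values, AUC is trapezoidal, and the optimal cutoff maximizes
sensitivity + specificity (ties prefer higher specificity, then the smaller
threshold). Defaults: pit 1.40, deep pit 2.00, OS 1.20, ONL 1.10; these are
synthetic calibration values, not clinically validated thresholds.

## Acuity models

The combined model is OLS of logMAR BCVA on {ONL, Age18, IRL, OS,
Age18·IRL, Age18·OS} with the fixed reference coefficients (1.128, −0.076,
0.396, 0.131, −0.449, −0.579, 0.206); `Age18` is 0 for ages ≤ 18 years.
The categorical model regresses BCVA on grade as a factor (reference 1a),
whose fitted values are grade means; rows in singleton grades have no
leave-one-out prediction and are excluded from cross-validated metrics with
a flag. Goodness of fit is reported in-sample and under leave-one-out
cross-validation (explicit refitting; the hat-matrix identity
`e_i/(1−h_ii)` serves as an independent oracle in tests). Cross-validated
adjusted R² is `1 − (1−R²_cv)(n−1)/(n−p−1)` with R²_cv computed from
held-out predictions; because the reference usage is ambiguous, the
in-sample adjusted R² is always reported alongside.

Stepwise selection is deterministic and bidirectional over 12 candidate
terms (three ratio main effects, sex, Age18, and their two-way
interactions): one add or drop per iteration, scored by the LOOCV Pearson
correlation (an SSE-based `criterion="r2"` is available), accepting a move
that improves the criterion beyond 1e-10 or ties it with fewer terms. On
zero-noise cohorts this recovers exactly the six reference terms. Note
that with a cross-validation-correlation criterion the empty model is never
preferred on pure-noise data (its leave-one-out predictions are perfectly
anti-correlated with the response), so the selector should be read as a
predictive-accuracy maximizer, not a sparsity device.

## Agreement statistics

Weighted Cohen's kappa uses Cicchetti–Allison (linear) weights
`w_ij = 1 − |i−j|/(k−1)` on the ordinal grade indices (1a…4 → 1…5);
degenerate marginals (single category) flag kappa undefined. Bland–Altman
reports bias, SD, limits of agreement bias ± 1.96·SD, large-sample CIs
(bias: ±t·SD/√n; LOA: ±t·SD·√(3/n) — the standard formulas, chosen because
the reference analysis does not state its CI method), and an OLS trend of
differences on pair means with an F-test (DFn = 1, DFd = n−2). Group
comparisons gate on per-group Shapiro–Wilk normality at P > 0.05: ANOVA
with Holm–Šídák-adjusted pairwise t tests when normal, otherwise
Kruskal–Wallis with tie-corrected Dunn post-hoc.

## Synthetic data

The generator emulates exactly the features the metrics measure. Each layer
thickness is a constant parafoveal baseline plus a unit-peak Gaussian bump
or pit centered on the fovea (IRL: 110 − pit·G, width 500 µm; OS: 28 +
elongation·G, width 300 µm; ONL: 60 + thickening·G, width 300 µm), stacked
into seven ordered surfaces with fixed spacers (inner segments 25 µm,
OPL+HFL 40 µm, IZ→RPE 15 µm) over a ±2.25 mm scan. The Gaussian shape
matches the single-term Gaussian used for the OS fit and gives every ratio
a closed form, so measurement error is attributable end to end. B-scans
render each surface as an axial Gaussian band (peak intensities 0.4–1.0,
width 4 µm ≈ an SD-OCT axial PSF) with seeded additive noise, clipped at
zero; bands that would merge under the chosen width are flagged.

Cohort tables draw the three ratios independently and uniformly over the
observed ranges (IRL 0.82–2.66, OS 0.90–2.40, ONL 0.90–2.89), sex
Bernoulli(0.5) with no acuity effect, ages uniform in 5–75 years with the
adult fraction 36/74, and BCVA from the fixed equation plus homoscedastic
Gaussian noise. The noise SD defaults to 0.22 logMAR, calibrated once by
Monte Carlo so the combined model's cross-validated adjusted R² averages
≈ 0.50 at n = 74 under these ranges; grade is derived from the true ratios
via the default cutoffs. A `per_grade` mode instead draws a grade from the
published frequencies (3, 23, 33, 10, 5 of 74) and samples ratios from
per-grade bands separated by a margin around the cutoffs (a negative
margin overlaps the bands to study adjacent-grade confusion). Geometric
shape inversion (`shape_for_ratios`) requires ratios ≥ 1 because bump
amplitudes are nonnegative; sub-1 ratios occur only in the tabular
generator.

What the generator does **not** emulate: nystagmus motion artifacts, OCT
speckle statistics, directional (pupil-offset) HFL reflectivity changes,
segmentation error (surfaces are exact), or axial curvature of the retina.
Passing tests therefore demonstrate correctness of the measurement and
statistics chain, not robustness to real-image segmentation failure.

## Problem sizes and numerical choices

Tests and the acceptance script use 74–300-row cohorts, 100-seed Monte
Carlo for the model comparison, and a 200-eye rendered sweep — sizes at
which every check completes in seconds while keeping Monte Carlo SEs well
below the asserted tolerances. Interpolation is linear throughout the
metric chain (matching the reference procedure); image resampling alone is
bicubic. Ties in argmax-style rules always break toward the scan center to
keep flat inputs deterministic. All randomness flows through
`numpy.random.default_rng` seeds; cohort generation is bit-reproducible
under a fixed seed.

## Limitations

Automatic layer segmentation and frame registration are out of scope — the
pipeline consumes segmentations as input. The grading cutoffs and the
1a/1b sub-cutoff are synthetic calibrations, not clinical values. The
reference interobserver kappa cannot be recomputed from published
information (the full 5×5 confusion matrix is not available), so the
agreement module is validated against oracles and synthetic raters
instead.
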