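# Methods

This note documents the models, numerical choices and limitations behind
`ki67eval`. It is the package's own account of its science; every number it
mentions is computed by the test suite or by `scripts/acceptance.py`.

## Coordinate model

Points are continuous (sub-pixel) pixel coordinates with the origin at the
ROI's top-left corner, x rightward, y downward — the convention of image
viewers whose multi-point exports the CSV reader accepts. A coordinate frame
is a pixel grid plus a physical resolution (µm/pixel); containment uses the
half-open intervals `[0, width_px) × [0, height_px)` so membership is
unambiguous. Frames describing the same physical region may differ in
resolution (detector mark-up images are resampled renderings of the ROI);
mapping between them is a pure axis-aligned scaling with factors
`target_px / source_px` per axis, plus an optional translation that defaults
to zero. Rotation and landmark registration are deliberately out of scope.
Building a mapping between frames whose physical extents disagree by more
than 1% is an error unless explicitly overridden; anisotropic scaling is
permitted but warned about, because capped matching assumes isotropic
distances.

## Capped one-to-one matching

The matcher solves: among injective partial assignments between reference
dots and detections using only pairs within τ, maximize the pair count, then
minimize total Euclidean distance. Implementation: a cost matrix with
forbidden entries (distance > τ) set to `(max(n_ref, n_det)+1)·τ + 1`,
solved by `scipy.optimize.linear_sum_assignment`, then any assignment pair
exceeding τ discarded. Because each feasible pair costs at most τ, one
forbidden entry always costs more than any redistribution of feasible
distances can save, so minimizing total cost maximizes the feasible pair
count first — a plain minimum-distance objective without this construction
would happily match nothing.

τ defaults to 15 µm and is configurable. It represents the maximum diameter
of a NET tumor-cell nucleus: annotators and tools place dots anywhere on the
nucleus, so two dots up to a nuclear diameter apart can mark the same cell.
The cap is specified in µm and converted to pixels through the shared
frame's resolution; the boundary is inclusive (distance = τ matches).

Determinism: scipy's solver is deterministic and the returned pair list is
canonically sorted, so repeated runs are identical. On exact distance ties
the solver's choice is taken as-is; the exhaustive verification oracle
(`match_oracle`, for ≤ 8 points per side, dynamic programming over
detector-use bitmasks) additionally breaks ties toward the lexicographically
smallest pair list. Equivalence between the two is asserted on pair count
and total distance over hundreds of random instances.

Stratified evaluation runs the matcher twice: over all points ignoring
labels, and independently over the positive-labeled subsets of both sides.
A cell detected in the right place but mislabeled therefore counts as TP in
the total stratum and FN (+FP if other positives exist) in the positive
stratum.

## Detection metrics and aggregation

Per match: `TP = |pairs|`, `FN` unmatched reference, `FP` unmatched
detections; precision, recall, FDR = 1 − precision and the harmonic-mean
F-score follow. Ratios with zero denominators are undefined and carried as
NaN — common in the positive stratum, where many low-proliferation ROIs
contain no positive reference cell — and are skipped by median aggregation
while pooled aggregation absorbs them by summing raw counts before dividing.
Pooled (sum counts, then derive ratios) is the default case-level
aggregation; median-of-ROI-ratios is available for tool-vs-tool comparisons.
Count agreement is additionally summarized as strict over/under/equal
tallies per ROI and an OLS regression of detector totals on reference totals.

## Ki67 scoring and grading

ROI score: `100 · n_positive / n_total` percent. Case score: positive and
total counts are summed across the case's ROIs *before* dividing —
equivalent to scoring the pooled annotation set, and different from the mean
of per-ROI percentages (0/50 and 5/150 give 2.5%, not 1.67%). Grades follow
the WHO bands for gastrointestinal NETs: G1 < 3%, 3% ≤ G2 ≤ 20%, G3 > 20%,
applied to the unrounded score because the 3% boundary separates clinically
distinct G1 and G2 tumors. A grade-change flag records when a detector's
case score falls in a different band than the reference's.

## Agreement statistics

**ICC.** Two-way mixed model, single measures, two fixed raters (reference
vs one tool), computed from the ANOVA mean squares of the n×2 table.
Consistency form ICC(3,1) = (MS_R − MS_E)/(MS_R + MS_E); absolute-agreement
form ICC(A,1) adds the rater variance term 2(MS_C − MS_E)/n to the
denominator. 95% confidence intervals follow Shrout–Fleiss for the
consistency form and McGraw–Wong (Satterthwaite df) for absolute agreement;
the significance test is the one-sided F test MS_R/MS_E against ICC = 0.
Both variants are always computed and reported side by side, with
consistency as the default, because the named two-way-mixed/single-measures
configuration does not pin down the agreement definition. Exactly identical
series return ICC = 1 exactly (the residual mean square is forced to zero,
which float dust in the sum-of-squares decomposition would otherwise
prevent). Tables with zero total variance are a degeneracy error. The
implementation is verified against a hand-coded ANOVA oracle to 1e-10 and
against `pingouin.intraclass_corr` (point estimates and CIs), and recovers a
known simulated intraclass correlation within ±0.03 at n = 5000.

**Bland-Altman, nonparametric.** Differences are oriented reference − tool,
so a tool that over-estimates produces negative differences. Bias is the
*median* difference; limits of agreement are the 2.5th and 97.5th
percentiles of the differences with linear interpolation between closest
order statistics (numpy's "linear", i.e. type-7, rule — fixed and
documented since percentile conventions differ). Appropriate for the skewed,
zero-inflated count and score differences this pipeline produces.

**Wilcoxon signed-rank, paired, two-sided.** Zero differences are dropped
and the effective n reported. The exact null distribution is used when
n_effective ≤ 25 and the absolute differences are tie-free; otherwise a
tie-corrected normal approximation without continuity correction. The
statistic reported is the smaller signed-rank sum. The exact path is
verified against full enumeration of sign patterns; exact and approximate
p agree to ~0.01 in the decision-relevant range at n = 25 (discrepancies up
to ~0.02 occur for central p-values).

## Synthetic data

The generator emulates the geometry of the target evaluation setting — a
200 µm square ROI at 0.23 µm/pixel (870 px) containing ~200 tumor nuclei
with a positive fraction around 3% — so every pipeline stage is testable
without slide images.

**Reference.** Dart-throwing with a hard-core constraint: uniform candidates
rejected while closer than `min_spacing_um` (default 6 µm) to an accepted
point; labels i.i.d. Bernoulli(p_positive). The hard core keeps the pattern
in the one-to-one regime the evaluation assumes, while 6 µm < τ leaves room
for ambiguous assignments in stress tests. Rejection is bounded
(configuration error on infeasible densities; a crude packing bound rejects
plainly impossible configurations up front).

**Detector error model**, applied in the fixed order merge → class-specific
dropout → split → jitter → label flip → clutter, so measured rates can be
related to configured ones. Merges replace a reference pair closer than
`merge_dist_um` by one detection at the centroid (positive if either member
is positive); each cell participates in at most one merge. Splits replace a
detection by two points straddling it at `split_offset_um`. Jitter is
isotropic Gaussian, redrawn (up to 100 times) to stay inside the frame.
Clutter is Poisson-many uniform points with a configurable positive
fraction and an optional exclusion radius around true cells
(`clutter_min_dist_um`).

**Interaction to be aware of:** a clutter point that lands within τ of an
unmatched (dropped) reference cell is matched in its place, so with uniform
clutter the measured recall exceeds 1 − dropout and the FP count falls below
the clutter mean. The exclusion radius exists precisely to create the clean
recovery regime (clutter ≥ τ from every true cell) in which measured FN/FP
rates converge to the configured dropout/clutter parameters; the recovery
checks use it, the realism presets set it to the hard-core spacing (6 µm —
clutter objects are distinct nuclei) and accept the rescue effect.

**Presets.** `non_ml` (conventional threshold/watershed segmenter: heavy
clutter, splitting of inhomogeneously stained nuclei, merging of overlapping
nuclei, aggressive positive calls) and `ml` (CNN-style detector: mildly
conservative dropout, modest clutter enriched for positive non-tumor cells,
rare label errors). Rates were fixed once from the per-stratum detection
profiles reported for commercial tools of each kind; tests assert only the
qualitative ordering (the `ml` preset is better on FDR, precision and
F-score in both strata, and its positive-stratum recall exceeds its
precision), not specific values.

**Study simulation.** The default study is 10 cases × 8 ROIs. The per-ROI
cell count is drawn as round(N(200, 25)) — fixed-size ROIs contain
"approximately", not exactly, 200 cells — and each case's positive fraction
is drawn uniformly from (0.002, 0.045), reproducing a low-proliferation
cohort that straddles the G1/G2 boundary. Without this between-unit
variation the reference count series would be constant and ICC undefined.
All seeds derive from a single study seed via `numpy.random.SeedSequence`,
making datasets byte-reproducible.

**What the synthetic data does not capture:** spatial clustering of positive
cells (labels are independent of position), staining-intensity continua
(labels are binary with flip noise), detector errors correlated with local
density or stain quality, and annotator subjectivity on faint nuclei.
Passing recovery tests therefore demonstrates correctness of the evaluation
machinery under known error rates, not detector performance on real tissue.
Because all simulated cases lie near the 3% grade boundary and the presets
over-call positives, simulated grade-change counts run higher than would be
typical of a real low-proliferation cohort.

## Problem sizes and tolerances

Oracle-equivalence checks use 500 random instances of up to 7 points per
side with random caps. Recovery checks use 80 ROIs × 200 cells (pooled
recall within ±0.03 of 0.90 under 10% dropout; pooled FP within 3 SE of the
clutter mean 20/ROI). The positive-fraction calibration uses 300 ROIs; ICC
parameter recovery uses 5000 pairs. The error-free detector must yield
exactly perfect metrics, ICC exactly 1 and zero Bland-Altman bias/limits
through the complete file-based pipeline.

## Known limitations

- One-to-one matching only; deliberate many-to-one or area/overlap (IoU)
  evaluation is out of scope, as is any image processing.
- The ICC model treats ROIs as independent targets; no account is taken of
  ROIs nested within cases (a hierarchical model would be needed).
- The comparison against the published 80-ROI evaluation of two commercial
  detectors requires that dataset to be obtained separately
  (`data/study_roi_counts.csv`); the corresponding test reports a failure
  until it is present.
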