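# ki67eval

Cell-level evaluation of automated Ki67 nucleus detection against a
pathologist reference standard.

## The problem

The Ki67 proliferation index — the percentage of tumor cells whose nuclei
stain positive for Ki67 — drives WHO grading of well-differentiated
gastrointestinal neuroendocrine tumors (NETs): G1 below 3%, G2 from 3% to
20%, G3 above 20%. Automated image-analysis tools can count the hundreds of
cells this requires, but validating them only on *totals* (cell counts or the
final score) can hide compensating errors: a tool may report the right number
of cells while detecting the wrong ones. A cell-level evaluation instead asks,
for every detected nucleus, whether it corresponds to a specific cell the
pathologist marked.

`ki67eval` implements that evaluation for dot-annotation data (one x,y point
per nucleus, labeled positive/negative), for anyone benchmarking nucleus
detectors against expert annotations:

- **annotations** — CSV/JSON I/O for point annotations (ImageJ multi-point
  style) with coordinate-frame validation;
- **transform** — axis-aligned rescaling of detector coordinates onto the
  reference grid when mark-up images were rendered at a different resolution;
- **matching** — distance-capped optimal one-to-one assignment;
- **metrics** — FDR, precision, recall, F-score per ROI and pooled per case;
  over/under-count tallies; count regression;
- **scoring** — Ki67 score per ROI and per case (summed counts, not mean of
  ratios) and WHO grade with grade-change flags;
- **stats** — two-way mixed single-measures ICC (consistency and absolute
  agreement) with 95% CI, nonparametric Bland-Altman (median bias,
  2.5th/97.5th-percentile limits), paired Wilcoxon signed-rank test;
- **synthetic** — a generator for reference ROIs (hard-core point process)
  and simulated detector outputs with configurable jitter, class-specific
  misses, clutter, splits, merges and label flips.

## The matching criterion

Let `R` be the reference dots and `D` the detections of one ROI, on a shared
pixel grid, and let τ be the maximum permitted match distance (default 15 µm,
about the largest diameter of a NET tumor-cell nucleus — both the pathologist
and the tools may place their dot anywhere on the nucleus). Among one-to-one
assignments using only pairs with ‖r − d‖ ≤ τ, `match_points` returns one
that first maximizes the number of matched pairs and then minimizes the total
matched distance (Hungarian algorithm on a cost matrix whose forbidden
entries carry a prohibitive cost). Matched pairs are TP, unmatched reference
dots FN, unmatched detections FP, and

```
precision = TP/(TP+FP)   recall = TP/(TP+FN)   FDR = 1 − precision
F = 2·precision·recall/(precision+recall)
```

Matching is done once over all cells and once restricted to the
Ki67-positive subsets; the per-ROI score is `100·n_pos/n_total`, and the
case score sums counts over the case's ROIs before dividing.

## Worked example

```python
from ki67eval import (ReferenceConfig, DetectorErrorModel, generate_reference,
                      simulate_detector, MatchConfig, stratified_match,
                      metrics_from_match, roi_score, grade)

ref = generate_reference(ReferenceConfig(p_positive=0.04, seed=7))
model = DetectorErrorModel(jitter_sd_um=1.0, p_fn_neg=0.10, fp_per_roi=15.0,
                           clutter_min_dist_um=6.0, seed=8)
det = simulate_detector(ref, model, source="detector")

total, positive = stratified_match(ref, det, MatchConfig(max_dist_um=15.0))
m = metrics_from_match(total)
print(f"all cells:  TP={m.tp} FP={m.fp} FN={m.fn} "
      f"precision={m.precision:.3f} recall={m.recall:.3f} F={m.f_score:.3f}")
mp = metrics_from_match(positive)
print(f"positive:   TP={mp.tp} FP={mp.fp} FN={mp.fn}")
sr, sd = roi_score(ref), roi_score(det)
print(f"Ki67 score: reference {sr.score_pct:.2f}% ({grade(sr).value})"
      f" vs detector {sd.score_pct:.2f}% ({grade(sd).value})")
```

prints

```
all cells:  TP=192 FP=6 FN=8 precision=0.970 recall=0.960 F=0.965
positive:   TP=8 FP=0 FN=0
Ki67 score: reference 4.00% (G2) vs detector 4.04% (G2)
```

The simulated ROI holds 200 nuclei; the detector misses 8 of them (10%
dropout, less the clutter points that happen to land within τ of a missed
cell and get matched in their place), adds 6 spurious detections, and its
Ki67 score lands within 0.05 percentage points of the reference — the
kind of compensation a cell-level evaluation makes visible.

## Command-line pipeline

```sh
ki67eval simulate --out study/ --seed 7            # 10 cases × 8 ROIs, two preset detectors
ki67eval evaluate --manifest study/manifest.json --max-dist-um 15 --out report/
```

`simulate` writes one CSV per ROI and source plus a `manifest.json`;
`evaluate` consumes any manifest in that layout (real annotations work the
same way) and writes `roi_metrics.csv`, `case_metrics.csv`, `scores.csv`,
`case_scores.csv` and `agreement.json` (ICC in both variants with CI,
Bland-Altman, Wilcoxon, count comparisons, regression line, grade changes).
Runs are byte-reproducible for fixed inputs and seeds.

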