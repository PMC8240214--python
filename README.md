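# oarconcord

Interobserver agreement analysis for radiotherapy organ-at-risk (OAR)
delineations: pairwise 3D contour-agreement metrics, a synthetic
multi-observer contouring-error simulator, and cohort statistics for
delineation quality assurance.

## The problem

In head-and-neck radiotherapy, normal structures near the target (parotid
glands, brainstem, spinal cord, mandible, cochleas, pharyngeal constrictor
muscles, ...) are outlined slice-by-slice on the planning CT. Different
clinicians draw visibly different contours for the same structure on the
same scan — interobserver variability (IOV) — which distorts dose statistics
and toxicity prediction. Delineation-QA studies quantify IOV by comparing
each observer's contour against a guideline-conformant reference contour and
asking whether observers who follow international consensus guidelines (ICG)
agree better with the reference than those who do not.

`oarconcord` implements the full analysis pipeline for such studies, and —
because real multi-observer contour sets are rarely shareable — a
synthetic-cohort generator with a controlled error taxonomy so the pipeline
can be exercised and validated end to end.

## Metrics

For a reference mask *A* and test mask *B* on one voxel grid:

- **DSC** (Dice similarity coefficient) = 2·|A∩B| / (|A| + |B|), computed on
  voxel counts. 1 means perfect overlap, 0 disjoint. DSC is biased with
  respect to volume (large structures score higher for the same boundary
  error), which is why distance metrics are reported alongside — and is a
  tested property of this package.
- **MSD** (mean surface distance, mm): the mean of the pooled symmetric
  multiset of nearest-point distances between the two boundary surfaces,
  {d(p, ∂B) : p ∈ ∂A} ∪ {d(q, ∂A) : q ∈ ∂B}.
- **HD95** (95 % Hausdorff distance, mm): the 95th percentile (linear
  interpolation) of that same multiset — a robust alternative to the maximum
  Hausdorff distance.

Surfaces are the centres of 6-connectivity boundary voxels; all distances
are Euclidean in millimetres, so anisotropic CT grids (e.g. 1×1×3 mm) are
handled exactly. Correctness of the fast KD-tree distance path is defined
by, and tested against, a brute-force all-pairs oracle.

The cohort layer summarizes a long-format results table per organ (median
and range of each metric over valid comparisons, delineation counts per
observer group), computes delineation rates, and compares the ICG and
non-ICG observer groups with a two-sided independent t-test (Welch by
default; Student optional), either pooling all delineations or averaging
per observer first.

## Worked example

The `demo` subcommand runs the whole pipeline — simulate a two-group cohort,
score every contour against its reference, summarize per organ, compare the
groups — into one run directory:

```sh
oarconcord demo --out demo --seed 7
```

This simulates 2 patients × 4 observers (2 guideline-following with 1.0 mm
boundary jitter, 2 others with 2.5 mm) × 3 organs, and writes NIfTI masks,
`manifest.json`, `scores.csv`, `summary.csv`, `comparison.json` and
`provenance.json`. The per-organ summary (`summary.csv`) reads:

```
organ      n_ok  dsc_median  msd_median_mm  hd95_median_mm  n_delineated_ICG/4  n_delineated_OTHER/4
BRAINSTEM  7     0.951       0.474          3.0             4                   3
MANDIBLE   7     0.882       0.833          3.0             3                   4
PAROTID    8     0.953       0.618          2.5             4                   4
```

i.e. per organ the median Dice overlap, median mean-surface-distance and
median HD95 across all scored contours, plus how many of each group's 4
slots (2 observers × 2 patients) were delineated at all. The group
comparison (`comparison.json`, pooled per delineation) prints:

```
mean MSD ICG = 0.28 mm,  mean MSD other = 1.26 mm
Welch t = -5.32, dof = 13.7, p = 1.2e-4
```

— the guideline group's contours sit on average ~1 mm closer to the
reference surface, significant at p < 0.05 even in this tiny demo cohort.
Larger cohorts use the same machinery via `oarconcord simulate`, `score`,
`summarize` and `compare-groups`, each of which also accepts real mask data
through the NIfTI + manifest interface.

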