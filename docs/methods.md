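# Methods

This note records the models, conventions and design choices behind
`oarconcord`, in the spirit of a statistical-software methods appendix.

## Geometry and data model

All masks live on an axis-aligned voxel grid with anisotropic spacing
(sx, sy, sz) in mm; the world position of voxel (i, j, k) is
`origin + (i·sx, j·sy, k·sz)`. The third axis is declared cranio-caudal
("axial slices"), matching CT convention. NIfTI affines must be
axis-aligned up to permutation and sign; oblique orientations are rejected
with an explicit error rather than resampled, because every metric in the
package assumes the two masks share one millimetre frame and silent
resampling would change the answer. Cross-grid comparisons always fail fast
(shape equality, spacing within 1e-6 mm).

Float volumes are binarized at > 0.5, which tolerates interpolated or
lossily stored files while remaining deterministic. An all-zero mask is a
legal "delineated but empty" record, distinct from the absence of a record
("not delineated"); the distinction propagates to the statistics, where
empty contours still count as delineations but contribute no metric values.

## Agreement metrics

**Surface convention.** The surface of a mask is the set of centres of its
6-connectivity boundary voxels: occupied voxels with at least one
face-adjacent background neighbour, where the volume edge counts as
background. The edge rule gives a cropped structure (a spinal cord reaching
the most caudal slice) a closed, well-defined surface. No sub-voxel surface
model is used: the convention is deterministic and oracle-checkable, and it
is the one commonly used in segmentation evaluation.

**Distances.** Directed distances are Euclidean nearest-point distances in
mm between boundary-voxel centres, computed with a KD-tree. The contract is
that they equal the brute-force O(n²) all-pairs scan bit-for-bit; the test
suite enforces this on hundreds of random mask pairs, including anisotropic
spacings.

**MSD.** Verbal definitions of mean surface distance are often
one-directional; `msd` uses the pooled symmetric mean (all distances from
∂A to ∂B together with all from ∂B to ∂A), which makes the statistic
symmetric in its arguments — a property the invariant suite requires — and
matches common practice. Both directed means remain available
(`msd_directed`, CLI `--directed`) for sensitivity analysis.

**HD95.** The 95th percentile of the same pooled symmetric multiset, with
linear interpolation between order statistics, not the max of two directed
95th percentiles. This is one unambiguous, reproducible definition; the
percentile is a parameter (`compare(..., percentile=...)`) for users who
need another convention. HD95 is bounded above by the exact Hausdorff
distance by construction.

**Empty/absent semantics.** Distances are never imputed: a missing or empty
contour yields status `NOT_DELINEATED` / `TEST_EMPTY` / `REF_EMPTY` /
`BOTH_EMPTY`, DSC is 0 where exactly one side is empty (no overlap), and
all distance metrics are NaN. Downstream statistics exclude undefined
values and report delineation counts separately, so missingness is visible
rather than penalized into the metric distributions.

## Synthetic cohorts

The generator exists because multi-observer contour sets from real QA
studies are not generally shareable; it reproduces the *statistical
structure* of such a study, not any patient's anatomy.

**Phantoms.** Ten head-and-neck OAR stand-ins as voxelized parametric
shapes: ellipsoids (parotid, submandibular gland, cochlea), a tapered
cylinder (brainstem), a thin cylinder cropped at the caudal grid edge
(spinal cord), a posteriorly open half-torus arch (mandible), ellipsoidal
slabs with a cylindrical lumen carved out (oral cavity, glottic area,
supraglottic larynx) and a thin posterior half-shell (pharyngeal
constrictors). Sizes are order-of-magnitude realistic (parotid ≈ 25 cc,
cochlea < 0.5 cc). Per patient, each organ's size parameters are scaled by
a seeded factor drawn uniformly in ±15 %, so cohort statistics are not an
artifact of one fixed shape.

**Error model.** Each observer applies, in a fixed order, the error modes
seen in delineation audits: omission; wrong-location gross error (an
equal-volume ball displaced by a configured distance, modelling e.g. a
cochlea delineated where there is no cochlea); surrogate-structure
substitution (a uniform mm dilation, modelling spinal *canal* delineated
instead of cord); systematic shift (integer-voxel translation with
per-axis normal draws); cranio-caudal extent errors that add or remove
whole axial slices (e.g. a supraglottic larynx carried ≈ 2–3 cm — 7 slices
at 3 mm — too far caudally, or a cord stopped several slices short);
inclusion of an adjacent substructure (a tangent ball union, modelling
teeth included with the mandible); and finally boundary jitter.

Boundary jitter is realized on the signed distance field: the field is
perturbed by a smooth zero-mean random field of standard deviation σ mm
(Gaussian-smoothed white noise, correlation length 10 mm by default,
renormalized to unit variance) and re-thresholded at zero. This guarantees
closed, voxel-consistent outputs with a single magnitude knob in mm. The
voxel-centre distance transform is shifted toward the surface by half the
finest voxel step so that sub-voxel σ still moves the boundary; on
anisotropic grids a small residual bias along the coarser axes remains, and
on coarse grids the *measured* MSD of a given σ is attenuated by
digitization (a 1 mm jitter on a 2.5 mm grid flips few voxels). The
guaranteed — and tested — relationship is monotonicity of MSD in σ, not a
1:1 calibration.

**Two-group design.** The default panel has 7 guideline-following (ICG)
and 7 other observers. ICG observers get 1.0 mm jitter, others 2.5 mm;
gross-error probabilities are an order of magnitude rarer than jitter
(0.01–0.04 per contour) and organ-specific (wrong-location cochleas only
outside the ICG group; canal-for-cord in both). Per-organ delineation
probabilities differ by group the way guideline audits report them:
guideline users delineate the lesser-known organs (cochlea 0.59 vs 0.26,
glottic area 0.48 vs 0.29, constrictors 0.44 vs 0.19, supraglottic larynx
0.41 vs 0.26, SMG 0.98 vs 0.69) much more often, and the cord less often
(0.63 vs 0.97) because canal-for-cord delineations are excluded from cord
analyses. These are configuration defaults extrapolated from small observer
counts, not measured prevalences; they are chosen once to make the
synthetic cohort qualitatively reproduce the expected pattern (lower group
MSD for guideline users), not to match any study's effect size.

**Determinism.** Every generator output is a pure function of (specs,
profiles, seed). Random streams are derived from entropy tuples
(seed, stream-tag, patient, observer-index), so adding an observer or organ
never perturbs other draws, and the pipeline's CSV/JSON artifacts are
byte-identical across reruns with the same config and seed.

## Cohort statistics

The scored cohort is a long-format table with one row per
(patient, observer, organ) slot, including not-delineated slots. Per-organ
summaries give the median and (min, max) of each metric over status-OK rows
(even-count medians are the midpoint of the central order statistics) plus
delineated counts and slot counts per group. Delineation rate is delineated
slots / total slots for an (organ, group).

The group comparison is a two-sided independent t-test on metric values of
the ICG vs other group. Welch's unequal-variance form is the default
(robust when group variances differ); Student's pooled form is available
for sensitivity. Two units of analysis are reported side by side:
`PER_DELINEATION` pools every valid contour of a group (the usual reading
of boxplot-style group comparisons, but pseudo-replicated because one
observer contributes many contours), and `PER_OBSERVER` first averages each
observer's rows and tests observer means. Undefined metric values are
excluded, never imputed. No multiple-testing correction is applied across
organs; the headline comparison is a single pooled test.

## Problem sizes and numerical choices

Default synthetic grids are 48×48×40 voxels at 2.5×2.5×3 mm (a 120 mm³
field of view), which keeps a 20-seed, 5-patient, 14-observer, 6-organ
validation cohort comfortably within a few minutes on one CPU while leaving
every structure several voxels across. Unit-spacing 50³ grids are used for
the jitter-calibration and sphere-bias checks. Distance-metric exactness is
asserted bit-for-bit at the level of the pooled distance multisets; scalar
reductions (mean, percentile) are compared to the oracle at 1e-12 relative
tolerance because summation order differs between implementations.

## Limitations

- Phantoms are convex-ish parametric shapes; real OARs have concavities,
  thin processes and intensity-dependent ambiguity that the simulator does
  not emulate. Passing tests demonstrate correct *metric and pipeline*
  behaviour, not clinical realism of the error magnitudes.
- The voxel-centre surface convention differs from marching-cubes or
  sub-voxel surface models; absolute MSD/HD95 values are comparable only
  between tools using the same convention.
- The jitter field is stationary and isotropic in mm; real observer error
  concentrates at ambiguous borders (cranio-caudal ends, blurry soft-tissue
  interfaces) and is only partly captured by the dedicated extent modes.
- DICOM RT-STRUCT polygon I/O, rasterization, registration and dosimetric
  consequences (DVH/NTCP) are out of scope; masks must arrive as NIfTI
  volumes on a shared grid.
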