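# Methods

## Problem setting

Automatic organ contouring (the motivating case: heart segmentation on
thoracic CT for radiotherapy planning) is usually evaluated with
geometric overlap and distance metrics, while its clinical fate is
decided by readers who accept or reject individual contours. This
package implements the analysis that connects the two: per-slice
metrics, reader-panel consensus, chance-corrected agreement between
metric thresholds and that consensus, and rank-based tests of whether
metric distributions differ between answer groups. A synthetic-study
generator supplies masks, degraded predictions and virtual readers with
known ground truth, so every stage can be validated end to end.

## Metrics

For truth $A$ and prediction $B$ (binary, same grid):

* Dice $= 2|A\cap B|/(|A|+|B|)$; precision $= TP/(TP+FP)$; sensitivity
  $= TP/(TP+FN)$; pixel accuracy $= (TP+TN)/N$.
* HD95: surface voxels are foreground voxels with at least one
  background face-neighbour (4-connectivity in 2D, 6 in 3D; the grid
  edge counts as background). The default statistic is *directed*: the
  95th percentile of distances from each prediction-surface voxel to
  the nearest truth-surface voxel. A symmetric option returns the max
  of the two directed percentiles. Distances are Euclidean on 0-based
  voxel indices; an opt-in spacing-aware mode scales each axis by the
  voxel size first (relevant when slice thickness differs from in-plane
  resolution). Percentiles interpolate linearly between order
  statistics at rank $p/100\,(n-1)$ ("type-7"); the same rule is used
  for quartiles so all reported quantiles share one convention.
  Computation uses surface point sets and a k-d tree, which is exactly
  equivalent to the definition and is cross-checked against an
  all-pairs brute-force oracle in the tests.

Degenerate inputs follow fixed conventions rather than erroring
mid-pipeline: both masks empty → Dice 1.0, HD95 0.0, accuracy 1.0;
exactly one empty → Dice 0.0, HD95 undefined; precision is undefined
for an empty prediction and sensitivity for an empty truth. Undefined
values are `nan` sentinels — never silently 0 — and are excluded from
downstream sweeps and statistics with a reported per-metric tally, so
input rows always equal analyzed + excluded.

## Fusion

2.5D pipelines produce one prediction per viewing plane; the fused mask
is foreground where strictly more than half the co-registered inputs
are. With an even input count an exact tie must be resolved explicitly;
the default resolves to background (conservative contours). Probabilistic
fusion (soft-map averaging, STAPLE) is out of scope.

## Reader consensus

Answers are ordinal: A (adjust, major mistakes), B (adjust, minor but
clinically relevant), C (accept, small irrelevant mistakes), D (accept,
very accurate); A/B dichotomize to reject, C/D to accept. Plain
four-category majority vote can fail (e.g. A,B,C), so consensus is
dichotomize-first: the binary majority decides accept/reject (always
defined for odd panels; an even-panel tie raises an explicit error), and
the reported consensus letter is the modal answer within the winning
class, modal ties broken toward the more severe letter. This agrees
with the plain majority whenever one exists.

## Threshold agreement

A threshold $t$ converts a metric into a binary rater: accept iff
value $\ge t$ for higher-is-better metrics (Dice, precision,
sensitivity, accuracy) or $\le t$ for HD95. Boundaries are inclusive
and the convention is recorded in every output. Cohen's kappa
$(p_o-p_e)/(1-p_e)$ is computed at every candidate threshold — the
sorted unique observed values plus one sentinel beyond each end, a grid
that dominates any coarser presentation lattice — and the curve's
argmax is reported. Kappa is undefined where $p_e=1$ (both raters
constant, equal marginals); undefined points are excluded from the
argmax, and a single-class consensus flags the whole curve degenerate.
Argmax ties break toward the stricter threshold (larger for
higher-is-better, smaller for HD95): when several thresholds agree
equally well with the readers, the conservative acceptance rule is
preferred. The no-rejection summary reports the best metric value among
rejected slices and the count of accepted slices strictly beyond it;
with no rejected slices at all it degenerates to the worst observed
value with all $n$ slices beyond, and is flagged.

## Group statistics

Metrics are skewed and bounded, so per-group location is the median
with 25th/75th quartiles (type-7). The Kruskal–Wallis statistic is
implemented from the rank formula with midrank ties,

$$H = \frac{\frac{12}{N(N+1)}\sum_i n_i(\bar R_i - \tfrac{N+1}{2})^2}
          {1 - \sum (t^3-t)/(N^3-N)},$$

referred to $\chi^2_{k-1}$; the critical value (7.81 at df 3,
$\alpha=0.05$) comes from numerical inversion of the regularized
incomplete gamma function (scipy). Writing $H$ out rather than
delegating keeps it oracle-testable; the tests cross-check it against
`scipy.stats.kruskal`, a permutation p-value, the squared standardized
Mann–Whitney statistic (two groups, no ties), and a null-calibration
simulation. All five metrics are tested without multiple-testing
correction; the report says so explicitly. The four-level A–D grouping
is the default test (df 3); the binary grouping is also available.

## Synthetic study

The generator emulates the statistical structure the analysis assumes,
not anatomy:

* **Masks** are star-convex radial blobs: base radius $r_0 \sim$
  0.18–0.30 of the smallest grid dimension, perturbed by two low-order
  sinusoids (amplitudes 2–10% of $r_0$), center jittered up to 4% of
  the grid, clipped to keep the shape strictly interior. Star-convexity
  guarantees connectivity; occupancy stays within 2–60% of the grid.
* **Degradations**, each scaling with a severity in $[0,1]$ (severity 0
  is the identity): rigid translation (≤ 5 voxels by default), smooth
  boundary jitter (spatially filtered Gaussian noise added to the
  signed distance, amplitude 2.5 voxels at severity 1), rough edges
  (independent single-voxel flips along the contour band), dropout (a
  ball of the object removed), and false-positive blobs (a spurious
  disjoint component). Severity is drawn per slice from Beta(1.5, 3) by
  default — a population skewed toward mildly degraded predictions, so
  roughly three quarters of slices end up acceptable, the shape of a
  realistic reader study.
* **Class imbalance**: exactly `round(empty_fraction·n)` slices (default
  20%) carry an empty ground truth — an exact count, not Bernoulli
  draws, so fixture sizes are deterministic.
* **Per-plane predictions**: each of the (default 3) planes is an
  independent degradation of the same truth, with seeds derived from
  the master seed; metrics are computed on the majority-vote fusion.
* **Readers**: latent quality $q = \sum_m w_m z_m + \varepsilon$, where
  $z_m$ are the five metrics z-scored across the study (so weights are
  comparable; undefined values are imputed with the study-worst
  observed value first), $\varepsilon \sim N(0,\sigma^2)$ independently
  per reader and slice, and three strictly increasing cutpoints
  $\tau_A<\tau_B<\tau_C$ map $q$ to A/B/C/D; a score exactly at a
  cutpoint takes the higher (better) category, so accept ⇔
  $q \ge \tau_B$. Defaults: weights (1.0, −0.6, 0.3, 0.3, 0.2) on
  (dice, hd95, precision, sensitivity, accuracy), cutpoints
  (−2.4, −1.1, 0.0), noise sd 0.35, three readers — chosen once to give
  an answer mix with D most frequent and A rarest and ~75% acceptance.
  `threshold_reader_model` builds the special case used for parameter
  recovery: unit weight on one raw metric, the accept boundary
  ($\tau_B$) at a hard threshold, zero noise.

Determinism: every generated artifact is a pure function of the seed
and parameters; sub-generators combine the master seed with a stable
per-component integer tag through `numpy.random.SeedSequence`, avoiding
stream collisions.

What the generator does **not** model: CT intensities or windowing,
anatomically faithful shapes, within-volume correlation between slices
(slices are i.i.d.), reader drift or fatigue, and systematic
disagreement between readers and the ground truth (e.g. ambiguous
anatomy at the organ boundary). Passing tests therefore demonstrate the
*analysis machinery* is correct and well calibrated — they do not show
that any particular metric threshold transfers to clinical data.

## Problem sizes and numerical choices

Validation uses sizes small enough to run comfortably on one CPU while
keeping the statistics meaningful: metric-oracle equivalence on 1000
random masks up to 16×16 (exact agreement), sweep optimality on 100
instances of 100 slices (exhaustive enumeration), threshold recovery on
a 500-slice study (recovered threshold within one candidate-grid step
of the generative 0.85, kappa exactly 1 in the noiseless case, and
strictly decreasing kappa across three reader-noise levels), and
type-I-error calibration of the H test over 2000 null replicates. The
acceptance script's default study uses 300 slices on a 64×64 grid.

## Known limitations

* The directed HD95 follows the "distance from predicted contour points
  to the nearest ground-truth contour point" reading; symmetric HD95 is
  available but not the default, and the two differ on asymmetric
  errors (a regression test documents this).
* Surface extraction is voxel-based; no sub-voxel/mesh surfaces.
* Quartiles are type-7 throughout; statistics packages that default to
  other quantile rules (e.g. SPSS) will differ slightly in group IQRs.
* Kappa confidence intervals, ROC/AUC analysis, post-hoc pairwise tests
  and multi-category (weighted) kappa are out of scope.
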