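# contourqa

Quantitative segmentation metrics — Dice, 95th-percentile Hausdorff
distance, precision, sensitivity, pixel-wise accuracy — are the standard
currency for reporting automatic contouring results, yet a high score is
no guarantee that a clinician would accept the contour. `contourqa` is a
toolkit for studying that gap: it relates per-slice metric values to the
accept/reject verdicts of a reader panel, finds the metric threshold
that agrees best with the readers, and tests whether metric
distributions differ between answer groups. Because real reader studies
are rarely shareable, the package ships a synthetic-study generator
(heart-like binary masks, controllable prediction degradation, virtual
readers) so the whole analysis can be exercised, validated and
benchmarked end to end without any clinical data.

It is aimed at researchers evaluating organ-at-risk auto-contouring
(e.g. heart segmentation on CT for radiotherapy planning) and at anyone
building quality-assurance gates on top of segmentation metrics.

## The analysis

For a ground-truth mask $A$ and prediction $B$ on the same grid:

- **Dice coefficient** $\mathrm{DC} = 2|A \cap B| / (|A| + |B|)$;
- **HD95**: the 95th percentile of the distances from each surface
  voxel of $B$ to the nearest surface voxel of $A$ (directed, in
  voxels; a symmetric variant takes the max of both directions);
- **precision** $TP/(TP+FP)$, **sensitivity** $TP/(TP+FN)$,
  **pixel-wise accuracy** $(TP+TN)/N$.

Readers rate each predicted contour A–D (A = major mistakes …
D = very accurate); the panel consensus is taken by majority vote and
dichotomized: A/B = reject, C/D = accept. A candidate threshold $t$
turns a metric into a second binary rater (accept iff value $\ge t$ for
higher-is-better metrics, $\le t$ for HD95); agreement with the reader
consensus is Cohen's kappa

$$\kappa = \frac{p_o - p_e}{1 - p_e},$$

swept over all observed metric values to find the kappa-maximizing
threshold. The *no-rejection* threshold is the best metric value among
rejected slices — every slice strictly beyond it was accepted.
Per-answer-group metric distributions are summarized as median (IQR)
and compared with the ties-corrected Kruskal–Wallis $H$ test against a
$\chi^2_{k-1}$ reference ($\chi^2_{3,0.05} = 7.81$ for four answer
groups). Multi-plane (2.5D) predictions are fused voxel-wise by
majority vote before any metric is computed.

## Worked example

```python
from contourqa import PipelineConfig, SyntheticStudyConfig, run_pipeline

cfg = PipelineConfig(mode="simulate", study=SyntheticStudyConfig(n_slices=101, seed=42))
report = run_pipeline(cfg)

curve = report.agreement_curves["dice"]
kw = report.kruskal_wallis["dice"]
print(f"best Dice threshold:  {curve['best_threshold']:.3f}  (kappa = {curve['best_kappa']:.2f})")
nr = report.no_rejection["dice"]
print(f"no-rejection Dice boundary: {nr['boundary_value']:.3f}  "
      f"({nr['n_beyond']} accepted slices beyond it)")
print(f"Kruskal-Wallis (Dice vs A-D): H = {kw['H']:.1f}, df = {kw['df']}, "
      f"critical chi2 = {kw['chi2_critical']:.2f}, p = {kw['p_value']:.2e}")
```

prints

```
best Dice threshold:  0.911  (kappa = 0.89)
no-rejection Dice boundary: 0.932  (67 accepted slices beyond it)
Kruskal-Wallis (Dice vs A-D): H = 82.1, df = 3, critical chi2 = 7.81, p = 1.09e-17
```

Reading: dichotomizing this simulated study at DC ≥ 0.911 agrees best
with the virtual readers' consensus (κ = 0.89); no slice with DC above
0.932 was rejected; and Dice differs strongly across the four answer
groups (H far beyond the 7.81 critical value). The binary group
summaries for the same run give median DC 0.964 (IQR 0.945–1.000) for
the 76 accepted and 0.896 (0.871–0.907) for the 25 rejected slices.

The same stages are available from the shell:

```sh
contourqa simulate --n-slices 101 --seed 42 --out study/
contourqa metrics --path study/masks --out metrics.csv
contourqa consensus --answers study/answers.csv --out consensus.csv
contourqa sweep --metrics metrics.csv --consensus consensus.csv --metric dice --out curve.csv
contourqa stats --metrics metrics.csv --consensus consensus.csv --out report.json
contourqa run --n-slices 101 --seed 42 --out out/   # everything at once
```

The threshold selector is also exposed as a scikit-learn estimator
(`KappaThresholdClassifier`), so it composes with sklearn pipelines and
model selection.

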