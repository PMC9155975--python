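# gastroseg

Level-set segmentation losses, CT texture features and recurrence risk
statistics for gastric-wall CT — exercised end-to-end on synthetic annular
phantoms and a synthetic patient cohort.

## The problem

After radical gastrectomy for advanced gastric cancer, a substantial fraction
of patients recur. Two quantitative questions surround the follow-up CT:

1. **Segmentation.** The gastric wall is an irregular annulus with *two*
   edges (inner, lumen-facing; outer, fat-facing). Classical two-region
   active-contour energies and plain cross-entropy training both tend to
   capture only one edge. This package implements the **level-set (LS) loss**
   — the Chan–Vese energy used as a differentiable training objective — and a
   **regularized level-set (LSR) loss** that compares the prediction to the
   ground truth through region means *plus* a direct pixel-fidelity term,
   which constrains the wall's internal detail:

   LS:  F(φ) = μ·length(φ) + χ·Area(φ) + δ₁·Σ(μ₀−c₁)²H(φ) + δ₂·Σ(μ₀−c₂)²(1−H(φ))

   LSR: F(φ) = (1/δ₁)Σ(G−c₁)²H(φ) + (1/δ₂)Σ(G−c₂)²(1−H(φ)) + (1/δ₃)Σ(G−φ)²

   with the smoothed step H(x) = ½(1 + (2/π)·arctan(εx)), evaluated on the
   centered field φ−½, and c₁, c₂ the H-weighted region means. Around the
   losses sit the standard companions: per-pixel Box–Muller noise
   augmentation Q* = Q + cos(180°+α₁)·√(−2·ln α₂) (geometric augmentation is
   a poor fit for gastric CT), global-average-pooling feature weights
   Wᵢ = GAP(Fᵢ)/Σⱼ GAP(Fⱼ), and Dice / IoU evaluation.

2. **Risk factors and texture.** Which covariates (age ≥ 60, tumor diameter
   ≥ 6 cm, TNM III/IV, chemotherapy, sex, location) are associated with
   recurrence — 2×2 cross-tabs, Pearson χ², odds ratios with Woolf CIs,
   multivariate logistic regression — and do first-order + GLCM texture
   parameters (mean, skewness, kurtosis, entropy, Haralick correlation) of
   the wall ROI separate recurrent from non-recurrent disease?

No patient images ship with the package. The `phantoms` module generates
irregular annular "gastric wall" slices with ground-truth masks, two contrast
phases, per-patient heterogeneity tied to a recurrence label, and a cohort
whose covariate frequencies default to a published 86-patient
recurrence/no-recurrence series, so every downstream module has a known
ground truth.

## Worked example

```python
import numpy as np
from gastroseg.phantoms import PhantomParams, generate_phantom, generate_cohort
from gastroseg.segmenter import SegmenterConfig, evolve_level_set
from gastroseg.metrics import dice, iou
from gastroseg.risk import analyze

# segment one phantom by LSR-driven level-set evolution
params = PhantomParams(size=96, outer_radius=30, wall_thickness=8,
                       boundary_irregularity=0.03, heterogeneity_sd=2.0, seed=7)
slc, gt = generate_phantom(params)
phi, log = evolve_level_set(slc, gt, SegmenterConfig(loss="lsr", iterations=300))
pred = (phi >= 0.5).astype(np.uint8)
print(f"Dice = {dice(gt, pred):.4f}, IoU = {iou(gt, pred):.4f}")

# regenerate the published cross-tabs and screen the risk factors
records, _ = generate_cohort(56, 30, exact=True, seed=1, with_images=False)
for r in analyze(records, ["age", "diameter", "tnm", "chemo"]):
    print(f"{r.factor:9s} chi2 = {r.chi_square:6.2f}  p = {r.p_value:.2e}  "
          f"OR = {r.odds_ratio:6.2f}  95% CI [{r.ci95[0]:.2f}, {r.ci95[1]:.2f}]")
```

Output:

```
Dice = 1.0000, IoU = 1.0000
age       chi2 =  24.70  p = 6.71e-07  OR =  12.05  95% CI [4.17, 34.77]
diameter  chi2 =  51.93  p = 5.76e-13  OR =  75.00  95% CI [17.37, 323.86]
tnm       chi2 =  40.34  p = 2.14e-10  OR =  33.94  95% CI [9.52, 121.05]
chemo     chi2 =  10.41  p = 1.26e-03  OR =   0.19  95% CI [0.06, 0.55]
```

Reading: the LSR evolution recovers the annular wall exactly on an
easy-regime phantom; in the regenerated cohort, age ≥ 60 multiplies the odds
of recurrence about 12-fold (χ² = 24.70 on the 44/12 vs 7/23 table), large
diameter and advanced TNM stage are strongly associated, and chemotherapy is
protective (OR < 1).

A console script mirrors the library:
`gastroseg simulate|augment|segment-evolve|train|evaluate|texture|risk|pipeline`
— e.g. `gastroseg pipeline --seed 4 --out-dir out/` runs phantom → augment →
segment → metrics → texture → risk and writes a hash manifest.

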