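# Methods

## Phantom model

Each synthetic slice emulates a single contrast-enhanced abdominal CT
acquisition of the stomach: a bright annular wall around a darker lumen on a
dark background, on a square grid (default 512×512; examples and the test
suite use 64–128 px grids, which preserve every geometric feature at a
fraction of the cost). The wall is the set of pixels between two closed
contours r_in(θ), r_out(θ); both carry a smooth radial perturbation — a sum
of random-phase low harmonics (orders 2, 3, 5) with relative amplitude
`boundary_irregularity` — drawn independently for the inner and outer edge,
so the wall has the distinct, irregular double edge that motivates the LSR
loss. Intensities are HU-like arbitrary units (no calibration claimed):
background 10, lumen 40, wall 130 by default, with the portal-venous phase
modelled as a fixed ×1.25 wall multiplier (the later acquisition enhances
the wall more; no pharmacokinetics). Within-wall heterogeneity is i.i.d.
Gaussian noise of standard deviation `heterogeneity_sd` added to wall pixels
only — the texture signal. All generators are pure functions of
(parameters, seed); masks are sets of whole pixels (row-major, 0-based,
pixel centers at integer coordinates) and never touch the image border.

The cohort generator draws categorical covariates per arm from configurable
frequency tables whose defaults equal the per-arm frequencies of a published
86-patient (56 recurrence / 30 control) gastric-cancer series; `exact=True`
replaces sampling by largest-remainder allocation so the cross-tabs hit
those counts precisely. Recurrence-arm phantoms get `heterogeneity_sd`
increased by `texture_effect` (default 5), which is what makes the texture
analysis recoverable. One slice per patient-phase is generated.

What the phantoms do *not* emulate: scanner noise physics and beam
hardening, partial-volume blur, 3-D anatomy, contrast timing, or
inter-scanner texture variability. A passing texture test therefore shows
the pipeline recovers a heterogeneity difference it planted, not that these
features transfer to any particular scanner.

## Noise augmentation

`insert_noise` adds, per pixel, σ·cos(180°+α₁)·√(−2 ln α₂) with
α₁ ~ U[0°, 360°), α₂ ~ U(0, 1]. The angle is read in degrees and the
logarithm is natural: the product is then exactly one Box–Muller branch, so
the perturbation is standard normal (the 180° shift only flips the cosine's
sign). σ (default 1) scales the perturbation; noise is applied to all
pixels, i.i.d.

## Losses

Both losses act on a prediction field φ ∈ [0,1] through the smoothed step
H(x) = ½(1 + (2/π)·arctan(εx)). Two conventions matter:

* **Centering.** H is evaluated at φ−½, so for sharp ε, H(φ−½) ≈ φ on
  near-binary fields and the perfect-prediction limit LSR(G, φ=G) → 0 holds.
* **ε** (default 100 for loss evaluation, 20 for evolution) sets the step's
  gradient at the crossing; 1/ε is the soft-boundary width in φ-units.

LS loss: μ·length + χ·Area + δ₁·Σ(μ₀−c₁)²H + δ₂·Σ(μ₀−c₂)²(1−H), where
length is the L1 norm of the forward-difference gradient of H (one-sided at
the boundary; for a sharp step it counts boundary edges) and Area = ΣH.
LSR loss: (1/δ₁)Σ(G−c₁)²H + (1/δ₂)Σ(G−c₂)²(1−H) + (1/δ₃)Σ(G−φ)². The
opposite placement of the δ weights (multiplicative in LS, reciprocal in
LSR) is kept exactly as each energy defines it. All weights default to 1.
The two losses are exposed separately; a weighted sum is a config option of
the segmenter.

c₁/c₂ are the H-weighted means of the reference field (image for LS, ground
truth for LSR). Because weighted means are stationary points of their
weighted least-squares objectives, the gradient terms arising from
∂c/∂φ cancel exactly (Σ(G−c₁)H = 0), so the "detached region means" scheme
and the exact gradient coincide; `lsr_gradient` is therefore a single
implementation, validated against central finite differences. Degenerate
fields (numerically all-inside or all-outside) raise rather than return
NaNs. A `smoothed_step_literal` variant exposing the printed constants
arctan(εx)/180 + 60 is kept for audit only; it is not a unit step and no
loss uses it.

## Segmentation backends

The *evolution* backend is deterministic projected gradient descent directly
on φ (init: the min–max-normalized image; clip to [0,1] each step; default
300 iterations, rate 0.2, with mild regularizer weights μ=0.1, χ=0.05 so the
fidelity terms dominate on normalized images). With the LSR loss it uses the
ground truth (training-style); with the LS loss it is classical Chan–Vese
evolution on the image alone, which is what `segment` runs on unseen slices.

The *network* backend is a deliberately tiny pure-numpy encoder–decoder that
exists to exercise the GAP weighting: four 3×3-conv + ReLU feature maps at
pooling scales 1/2/4/8 (near-identity kernel init), fused by the normalized
GAP weights Wᵢ = GAP(Fᵢ)/Σⱼ GAP(Fⱼ) (maps rectified first so the weights are
well-defined; weights treated as constants in backprop), then an affine
sigmoid head. Training is full-batch gradient descent on the per-pixel mean
of the configured loss (the mean keeps gradient magnitudes independent of
image size). Image dimensions must be divisible by 8. Soft masks are
binarized at 0.5 throughout.

## Texture features

Mean, skewness m₃/m₂^{3/2} and kurtosis m₄/m₂² use population moments;
kurtosis is Pearson-convention (normal → 3), the convention consistent with
near-normal CT ROIs scoring ≈ 3.1–3.2. Entropy is −Σp·log₂p (bits) over a
histogram quantized uniformly between ROI min and max, 64 levels by default.
The GLCM accumulates distance-1 pairs in the four standard directions, both
pixels required inside the ROI, symmetrized and normalized; correlation is
the normalized Haralick form (∈[−1,1]), with a raw-covariance variant behind
a flag since some commercial packages print an unnormalized value on an
arbitrary scale.

ROI choice for cohort analysis: a rectangular patch — the wall mask's
bounding box plus a 4-px margin — as is common in clinical texture tools.
This matters numerically: min–max quantization of a *pure* Gaussian sample
is scale-invariant, so a wall-only ROI would normalize the heterogeneity
away; the rectangular ROI includes the fixed background/lumen/wall intensity
plateaus, which anchor the quantization range and make entropy monotone in
the wall's heterogeneity sd (measured ≈ +0.24 bits for sd 5 → 10 at 96 px).
Min–max binning also gives the shift-equivariance property: adding a
constant to all pixels moves the mean only.

## Risk statistics

Tables are rows = (recurrence, no-recurrence) × columns = (at-risk level,
reference level); location is 2×3. The 2×2 χ² uses the closed form
n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) without continuity correction by default
(the regenerated tables have all expected counts > 5; Yates by flag), wider
tables the general Pearson statistic. Percentages are rounded half-up to two
decimals, the convention matching the published tables except one value the
source prints as 89.28 where 50/56 rounds to 89.29. Odds ratios are ad/bc
with Woolf CIs and Haldane–Anscombe +0.5 when a cell is empty. The logistic
model is an ordinary MLE (Newton/IRLS, tolerance 1e-8, ≤100 iterations) with
Wald inference; exploding coefficients are reported as perfect separation
with an L2-penalized fallback behind a flag. With a single binary predictor
the fitted coefficient equals the log odds ratio of its 2×2 table — used as
a cross-check between the two routes. Published multivariate coefficients
for this design are not reproducible without individual-level joint
covariate data, so none are asserted; the module reports standard logistic
outputs.

## Sizes, tolerances, determinism

Problem sizes used by the tests and the acceptance script — 96-px phantoms,
20-image segmentation sets, 30/30 texture cohorts, n = 2000 logistic
cohorts, 10⁵-pixel noise samples — were chosen as the smallest at which each
property is comfortably resolved; the generator's 512×512 default remains
the realistic acquisition matrix. Oracle agreement for the losses is
asserted at 10⁻¹⁰ relative (measured ≈ 10⁻¹⁵), the gradient at 10⁻³ against
central differences with step 10⁻⁵. The logistic recovery margin (±0.15 at
n = 2000) is about 1.5 standard errors per coefficient, so it is a
fixed-seed check, not a guarantee over all seeds. Every stochastic component
takes an explicit integer seed; one global seed derives per-module
substreams by hashing, and pipeline reruns are hash-identical.

## Known limitations

Single 2-D slice per patient-phase; no 3-D level sets, no multi-phase
(>2-region) Chan–Vese, no signed-distance reinitialization; no surface-
distance segmentation metrics; the network backend is a minimal vehicle for
the losses, not a competitive segmenter; texture features are not
IBSI-standardized; phantom realism limits any claim about real scanners.
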