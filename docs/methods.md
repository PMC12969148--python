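# Methods

This note documents the models, parameter choices and numerical
conventions behind lesionforge, what the synthetic-data generator does
and does not emulate, and the known limitations of the desk-scale
implementation.

## Synthetic dermoscopy generator (`synthgen`)

Every experiment in the package runs on generated scenes, so the
generator is first-class, tested code rather than a fixture.

**Lesion geometry.** A lesion boundary is a radial function
`r(θ) = R·(1 + irregularity · Σ_h a_h cos(hθ + φ_h))` with harmonics
`h = 2 … H+1`, amplitudes `a_h ∝ 1/h` normalized so the peak deformation
is at most `0.45 · irregularity` (the boundary can never self-intersect),
and seeded phases. Asymmetry is anisotropic axis scaling
(`×(1+0.45a)`, `×(1−0.25a)`) followed by a shear of `0.5a`. This gives
independent, monotone control of the two shape descriptors the analyses
use: compactness `P²/4πA` grows with `irregularity` (verified over 50
seeds) and the reflection-asymmetry index grows with `a`. The polygon is
rasterized, hole-filled, reduced to one 4-connected component, and must
fit the canvas with a 2 px margin (a sizing error otherwise).

**Appearance.** Pigment is a per-pixel blend of a class palette driven by
a smoothed Gaussian random field, darkened toward the lesion core, with
additive texture noise (default SD 0.02–0.03); skin is a fixed tone with
small seeded variation. Corruptions — multiplicative colour cast, a
linear illumination ramp of amplitude `±g/2`, and quadratic-Bézier hair
strokes (width ≤ 3 px, multiplicative darkening) — are applied on top,
never touching the mask raster; the pre-hair image is returned as the
restoration ground truth.

**Study conditions.** The default class priors make the *benign majority*
dark and regular and the *melanoma minority* low-contrast (pigment close
to the skin tone), asymmetric and border-irregular — the clinically hard,
underrepresented case that motivates class-balanced augmentation.
Experiments use a 20% minority (40 benign / 10 melanoma training images),
inside the 15–25% range typical of public dermoscopy collections.

**What it does not emulate:** photorealistic skin texture, device optics,
ruler marks and gel bubbles, and the full diversity of real pigment
networks. Passing tests therefore demonstrate the *mechanisms* (that
rebalancing helps a minority the model underfits; that restoration
recovers a known clean image), not clinical performance.

## Preprocessing chain (`preprocess`)

Stage order is `shades_of_gray → hair_remove → normalize → CLAHE/Otsu
localization → crop/resize → morphology enhancement`. Illuminant and
artifact corrections run before the statistics-based normalization so
channel statistics are estimated on artifact-free pixels; the order is
configurable, including the literal normalize-first ordering.

* Channel normalization standardizes to zero mean / unit population SD
  with an ε-guard mapping constant channels to exact zeros, then min–max
  rescales globally to [0, 1] (downstream stages assume that range).
* Otsu's threshold maximizes `ω₁μ₁² + ω₂μ₂²` over 256 histogram-edge
  candidates (identical argmax to the between-class-variance form);
  ties break toward the lower threshold; the lesion is taken as the
  darker class, with a polarity flip when the mask covers over half the
  frame. Exhaustive search is the test oracle.
* Grayscale is Rec.601 luma throughout; the Laplacian is the 4-neighbour
  stencil; the morphological gradient is `dilate − erode` with a disc.
* Shades of Gray estimates the illuminant per channel as
  `E_c = (mean |I_c|^p)^{1/p}` (default `p = 6`), divides, and rescales
  to max 1; the operation is exactly idempotent and approaches the
  white-patch estimate as `p → ∞`.
* Hair detection is a union of black-hat responses over four linear
  structuring elements (length 9, threshold 0.06). Dark lesion rims also
  respond (their chords are locally shorter than the line), so detected
  components are kept only if their extent exceeds 1.5× the line length —
  a rim artifact's extent is bounded by the line length itself, while
  hairs run much longer. The surviving mask is dilated by 1 px and filled
  by iterative 4-neighbour mean diffusion (tol 1e-4, ≤ 500 sweeps), which
  provably never alters pixels outside the mask. The CLAHE clip limit
  (0.01) and tile size (8) are package defaults; no canonical values
  exist for this chain.

## Latent augmentation (`moglisa`)

One dense autoencoder over lesion-masked images serves as both the
feature extractor and the decoder (tanh hidden layers, linear latent,
sigmoid output, Adam on MSE, fully seeded). It is trained on the
*minority subset*: decoded interpolants must stay on the minority
appearance manifold — training it on the full set measurably pulls
synthetic melanoma toward majority pigment and erases the augmentation
benefit.

**Covariance-preserving interpolation.** After whitening with
`Σ^{−1/2}`, cluster members are treated in polar form: the direction is
spherically interpolated (at parameter `1−α`, so `α = 1` returns the
first endpoint, matching the linear convention) and the norm
geometrically (`|u_a|^α |u_b|^{1−α}`). For an isotropic whitened cloud
this preserves both the direction distribution and the norm marginal,
hence the cluster's full second moment; linear blending shrinks it by
`α² + (1−α)²`. Antipodal directions (angle within 1e-6 of π) and
zero-norm endpoints fall back to whitened linear interpolation, flagged.
The trace is recovered within ~7% at α = 0.5 on a k = 8 standard-normal
cluster (the residual gap is the chi-norm geometric-vs-arithmetic mean
difference, which shrinks with k).

**Synthesis and filtering.** Interpolated latents are decoded; a mask is
derived by Otsu on the central region (outer 10% ring excluded), darker
side, largest component, holes filled; the lesion is composited onto the
parents' mean background colour. Candidates pass iff `CDS ≤ δ_c`
(default 0.2; experiments at tiny decoder scale use 0.35, inside the
customary 0.1–0.3 neighbourhood) and `S_edge ≥ δ_s` (default
data-relative: the 25th percentile of real lesions' sharpness, which is
scale-invariant). Filtering is deterministic and monotone in the
thresholds. `α ~ U(0.25, 0.75)` — the demonstrated operating range of
the interpolation ratio.

**Class balancing.** `N_T = min(max(N), N_cap)`; deficits are filled per
class from same-cluster parent pairs with an attempt budget of 20 per
sample; a shortfall warns, never silently truncates. Original records
are never modified; synthetic records are tagged with parents, α and
filter scores, and augmentation reads only the training split.

**Autoencoder scales.** Two documented operating points: a cheap AE
(32×32 input, 96 hidden, 60 epochs) for training-set augmentation — the
per-pixel surrogate consumes 32×32 features, so higher decoding
resolution adds nothing to the Dice-gain experiment — and a high-fidelity
AE (64×64 input, 192 hidden, 250 epochs) for the descriptor-level
plausibility analysis, where synthesis must be compared to real lesions
at the native resolution.

**Plausibility findings at desk scale.** With the high-fidelity AE the
shape descriptors (asymmetry index, border irregularity) of synthetic
minority lesions deviate only mildly from the real distributions (mean
relative deviations of a few percent to ~30%, with the Mann–Whitney test
retaining them on some seeds), while the photometric descriptors (colour
variance, texture contrast) are consistently and strongly rejected: a
dense MSE decoder leaves structured reconstruction error that inflates
within-lesion variance. This is an
expected limitation of the decoder-only synthesis path — the
conditional-GAN refinement that would restore photometric realism is
implemented only as a loss computation (with a fixed-seed random convnet
standing in as the perceptual feature map) and is not trained at full
scale here.

## Evolutionary optimizer (`gmfdef`)

Genes are log-continuous, continuous, integer or categorical.
Multiplicative mutation acts on all numeric kinds (integers rounded half
away from zero, everything clamped); categorical genes are resampled
uniformly with probability `min(1, σ)`, preserving the "σ controls
exploration" semantics. The feedback combination uses the printed
cross-weighting — the better partner's fitness weights the *other*
genome — with a `swap_alpha_beta` switch for the conventional reading;
`α + β = 1` exactly, with a 0.5/0.5 fallback when both fitnesses vanish.

Fitness normalization is min–max over the generation's selection pool
(parents ∪ candidates); a degenerate metric range contributes the
neutral 0.5. Because fitness is renormalized per generation, values from
different generations are not comparable; the historical-best anchor is
therefore the current population's fitness argmax (elitist selection
keeps the global best in the pool). Survivor selection adds whole Pareto
fronts, truncating the overflowing front by a per-objective
diversity-gap score (boundary members infinite, gaps normalized by
pool-wide objective ranges, degenerate ranges contribute 0), with
`(diversity, fitness, id)` lexicographic tie-breaking for determinism.

The feedback controller treats an `ε = 1e-4` exceedance of the best-ever
fitness as improvement; after 3 stagnant generations it raises σ by 1.5×
(capped at 1.0) and steps `p_mut` up by 0.1; on improvement it decays σ
by 0.97 (floored at 0.15) and steps `p_comb` up. The gentle decay and
high floor are deliberate: the improvement signal rides on renormalized
fitness and is noisy, and an aggressive decay collapses the mutation
scale before the 20-generation budget is spent; the defaults were
calibrated on the analytic toy benchmark (`dice = 1−x²`, `iou = 1−y²`,
`ba = 1−(x−y)²/2`, `hd = 1+x²+y²`, optimum at the origin), where the
optimizer's final front beats equal-budget random search by Monte-Carlo
hypervolume (shared seeded sample, origin reference) in ≥ 8 of 10 seeds.
Exact duplicates of a parent (neither operator fired) are not
re-evaluated.

The surrogate evaluation target is a per-pixel MLP over colour and
local-context features at 32×32 (width/depth/window/learning rate mapped
from the genome), trained full-batch with Adam in seconds — it exposes a
realistic hyperparameter response surface without GPU training.

## Metrics (`metrics`)

Pixel-count confusion metrics with the benign two-empty-mask convention
(Dice = IoU = 1); undefined ratios return an explicit flagged NaN, never
a silent number. Boundaries are 8-connected boundary pixel sets; boundary
accuracy is the symmetric tolerance-band recall (default 2 px) and the
Hausdorff distance is the exact sup–inf form, both computed via distance
transforms with all-pairs brute force as the test oracle. SSIM uses a
7×7 uniform window, `k₁ = 0.01`, `k₂ = 0.03`, `L = 1`, reflective
borders. PCP tiles the raster (tail tiles kept), counts both-empty
patches as correct, threshold 0.5 by default. Descriptors: asymmetry is
1 − the best reflection overlap about the two principal axes (computed on
pixel-center coordinates, hence translation-invariant); compactness uses
the Crofton perimeter; boundary smoothness is `1/(1+var κ)` on a
64-point arc-length-resampled contour; texture contrast is a masked
co-occurrence contrast (offset 1, 4 directions, 16 levels, only pairs
fully inside the mask) and texture entropy the Shannon entropy of the
16-bin masked histogram. Masks under 5 px are flagged undefined.

## Orchestration (`cli`)

Stratified splitting (default 70/15/15) uses cumulative-floor allocation
so global split sizes are exact while every class stays within one
sample of its proportion; splitting always precedes augmentation and
only the training manifest is ever augmented (the leakage guard is
structural: the augmenter receives no other manifest). `run_experiment`
supports multi-seed mode (mean ± SD reporting) and `run_ablation` the
2×2 augmentation × optimization grid. Run manifests record the config
snapshot, artifact hashes and per-stage provenance.

## Problem sizes

The default experiment and verification scales are: 5 000 interpolation
pairs on a k = 8 cluster; 10 optimizer repeats of 20 generations ×
population 10; 20 hair-restoration scenes at 80×80; 5 seeds of the
minority-Dice experiment (50 training / 20 test images at 64×64); 30
synthetic lesions for the plausibility analysis. These sizes give stable
Monte-Carlo estimates while keeping any single analysis in the
minutes-not-hours range on one CPU.

## Known limitations

* The autoencoder is dense, not convolutional; at 64×64 it memorizes and
  blends rather than generalizes. That is sufficient (and intended) for
  within-cluster interpolation of a small minority set, but photometric
  realism is limited (see the plausibility findings above).
* The cGAN synthesis path is a loss computation with frozen tiny nets,
  not a trained generator.
* The surrogate segmenter is a per-pixel classifier: it measures
  data-level effects (class balance, colour coverage) well, but has no
  spatial receptive field beyond its blur features, so architecture-level
  effects are only coarsely represented in the optimizer's response
  surface.
* Boundary accuracy and the "asymmetry index" follow documented
  formalizations chosen here; other operationalizations exist in the
  dermatology literature.
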