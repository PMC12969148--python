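# lesionforge

Class-balanced dermoscopic lesion segmentation toolkit: morphology-guided
latent augmentation, geometric-mean evolutionary optimization of
segmentation configurations, a six-stage preprocessing chain, and a full
segmentation/morphology metric suite — exercised end to end on a built-in
synthetic dermoscopy generator, with no external datasets or GPU.

## The problem

Public dermoscopy datasets are heavily imbalanced: melanoma — the lesion
class where a missed detection matters most — is typically only 15–25% of
the samples. Segmentation models trained on such data underperform
exactly on the minority class, and the usual pixel-level augmentations
(flips, rotations) add no new lesion morphology. This package implements
two data- and model-level remedies and the instrumentation to measure
them:

**Morphology-guided latent augmentation.** Minority lesions are encoded
(lesion-masked, background suppressed via `x ⊙ y`) into a latent space by
an autoencoder trained on the minority subset `D_min`. New samples are
drawn by interpolating *pairs of real latents within a morphology
cluster*. Plain linear blending `z̃ = α z̃_a + (1−α) z̃_b` shrinks the
cluster's second moment by `α² + (1−α)²` and produces over-average,
feature-smoothed lesions. Instead, each cluster's empirical covariance
`Σ_m = 1/(n−1) Σ (z̃_i−μ_m)(z̃_i−μ_m)ᵀ` defines a local geometry: latents
are whitened with `Σ_m^{−1/2}`, the *direction* is interpolated on the
unit sphere and the *norm* geometrically, then un-whitened — which
provably preserves the cluster covariance (trace recovered within a few
percent in Monte-Carlo checks, versus the 2× shrinkage of linear
blending). Decoded candidates are filtered by the Convexity Defect Score,
`CDS(M) = (area(hull(M)) − area(M)) / area(M) ≤ δ_c`, and a minimum
boundary edge sharpness `S_edge = mean_{p∈∂M} |∇x̂(p)| ≥ δ_s`, and added
until each class reaches `N_T = min(max(N), N_cap)`.

**Geometric-mean feedback evolution (GM-FDEF).** Segmentation-model
hyperparameters (learning rate, attention window, embedding width, depth)
are evolved with multiplicative mutation `Θ·exp(η), η ~ N(0, σ²)`
(scale-invariant for log-scaled genes), a feedback combination
`C = α·Z + β·H` with the historically best configuration `H` and
fitness-ratio convex weights `α = F(H)/(F(Z)+F(H))`, fitness
`F_GM = (M'_Dice · M'_IoU · M'_BA · M'_{1/HD})^{1/4}` over min–max
normalized metrics (so collapsing any single metric annihilates the
score), non-dominated Pareto sorting with diversity-gap truncation, and a
stagnation/improvement controller on `σ`, `p_mut`, `p_comb`.

All evaluation metrics (Dice, IoU, sensitivity/specificity/precision,
tolerance-band boundary accuracy, Hausdorff distance, windowed SSIM,
proportion of correct patches) and the dermatology-inspired descriptors
(asymmetry index, border irregularity `P²/4πA`, area/perimeter ratio,
boundary smoothness, colour variance, texture contrast/entropy) are
implemented in `lesionforge.metrics`.

## Worked example

```python
from lesionforge import cli

result = cli.minority_dice_experiment(seed=0, out_dir="scratch/demo")
print(result)
```

This generates an imbalanced synthetic training set (40 benign / 10
melanoma — a 20% minority), an independent balanced test set, trains the
surrogate segmenter with and without MoG-LISA rebalancing, and prints the
minority-class test Dice of both:

```
{'baseline_minority_dice': 0.41200063685872906,
 'augmented_minority_dice': 0.796510839671974,
 'gain': 0.38451020281324494}
```

The low-contrast melanoma minority is segmented poorly by the baseline
(Dice ≈ 0.41); filling the class deficit with covariance-preserving
synthetic lesions nearly doubles it (Dice ≈ 0.80). Averaged over five
seeds the gain stays large and positive (≈ +0.26 at seed set 10–14).

The command-line interface wraps the same library:

```bash
lesionforge synth --seed 1 --out data/           # synthetic dataset + manifest
lesionforge preprocess --in data --out clean     # enhancement chain
lesionforge augment --manifest data/manifest.csv --plan-cap 80 --seed 1 --out aug
lesionforge optimize --gens 20 --pop 10 --seed 1 # GM-FDEF on the toy surface
lesionforge evaluate --pred P --truth T --out metrics.csv
lesionforge ablate --seed 1 --out runs/ablation  # 2x2 augment x optimize grid
```

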