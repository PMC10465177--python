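# Methods

This note records the models behind each stage, the defaults and why they
were chosen, and what the synthetic data can and cannot establish.

## Synthetic organoid generator

A generated acquisition is an anisotropic ellipse (the organoid body) on a
vertical light-to-dark background gradient, with three appearance layers:

- **rim** — a band of width `rim_width` just inside the boundary, brightened
  and speckled (Gaussian texture of amplitude `rim_texture_amplitude`,
  default 18 intensity units) to mimic the neuroepithelial margin;
- **halo** — sparse dark dots in an annulus outside the body
  (`halo_density`, default 0.02), mimicking dispersed cells;
- **artifacts** — optional bright streaks (`artifact_count`), mimicking
  acquisition defects.

Degradation (Gaussian blur, additive Gaussian noise) is applied last and the
output is clamped to 8-bit. The ground-truth mask is the *exact* discrete
ellipse: a `boundary_wobble` parameter can add low-frequency undulation, but
it defaults to 0 so that the mask is independently verifiable by a
point-in-ellipse scan. Every generator is a pure function of (parameters,
seed); dataset-level seeds are spawned from a master `SeedSequence`.

Default study conditions follow the workflow the toolkit emulates: 40
original images, 250×250 px, six loss groups of 40 synthetic images each
(280 evaluated images, 240 synthetic), eight experts, so each group
collects 8 × 40 = 320 decisions.

The simulated expert draws, per image: a pass (probability `pass_prob`),
otherwise an error with the group's probability (`fp_prob_by_group` for
synthetic groups, `fn_prob` for originals). Decision times are lognormal
per category; the defaults put the error median (3.5 s) above the correct
median (2 s) so the "hesitation is longer on errors" signature is present
and recoverable. Lognormal is a modelling choice (positive support, right
skew), not an empirical fit — no decision-time distribution is documented
for the real sessions.

**What passing tests do not show:** the generator reproduces the geometry
and tonal layout of bright-field organoid images, not their biology or
optics. Metric values on generated data are in plausible regimes but are
not comparable to values measured on real acquisitions; parameter-recovery
results (e.g. configured FP rates recovered within binomial error) validate
the analysis code, not human behaviour.

## Adversarial autoencoder

No reference architecture accompanies the loss definitions, so the package
fixes a standard AAE topology at desk scale: dense encoder
(input → 128 tanh → latent 64), mirrored decoder with sigmoid output,
latent discriminator (64 → 32 tanh → 1 sigmoid), all trained with Adam
(lr 10⁻³) in numpy with fully deterministic seeding.

Per step:

1. **Reconstruction** — the gradient of the configured loss (BCE, BCE+L1
   with α = 10⁻⁴, LS, Poisson with ε = 0.25, Wasserstein, perceptual
   Wasserstein) plus a pixelwise-MSE backbone term (`recon_weight`, default
   1). The backbone matters for the two transport losses: they compare
   *intensity distributions* and are blind to pixel position, so alone they
   cannot drive reconstruction; anchored, they act as distribution-shaping
   terms. For the pixelwise losses the anchor is nearly redundant.
2. **Latent adversarial game** — the discriminator learns prior-vs-encoded
   (BCE), then the encoder is updated through the frozen discriminator to
   fool it (`adv_weight` 0.05). This pulls the latent cloud toward N(0, I)
   so that decoding prior draws yields images.

The Wasserstein estimator is the exact 1-D primal coupling: sort both
flattened batches and average |Δ| (order 1) or Δ² (squared ground
distance). The "perceptual" variant is read as the squared-ground-distance
transport — the only reading consistent with the printed form; the
alternative reading (normalising the loss value) is noted but not adopted.
No gradient penalty is applied. BCE probabilities are clipped at
δ = 10⁻⁷, so the BCE of a perfect prediction is the documented floor
−log(1−δ) rather than exactly 0.

Defaults are the study conditions (2 000 epochs, 250×250); tests and the
acceptance script use a desk-scale profile (32–64 px, ≤ 100 epochs, 8–40
images), which is enough to exhibit every contract (reconstruction MSE
strictly decreases under all six losses, determinism, in-range synthesis)
but deliberately not enough for photorealistic output.

## Metric suite

- **FID** is computed on pixel-statistic features — per image: mean, std,
  and a flattened 8×8 anti-aliased thumbnail — with a Gaussian fit per
  group and the closed-form Fréchet distance. This follows the
  pixel-statistic definition of the group means (no Inception network) and
  keeps values in the ~0.5–1.5 regime; the feature map is injectable.
  Singular covariances get diagonal loading (10⁻⁶) with a warning.
- **SSIM** uses whole-image statistics with the standard constants
  K₁ = 0.01, K₂ = 0.03, dynamic range 255 (the constants are not specified
  numerically anywhere upstream).
- **UQM/UQI** reads the cross term as the covariance σ_og — the standard
  universal quality index, and the only reading for which identical
  non-constant images score 1. Two constant images are a documented limit
  (1 if equal, else 0, with a warning).
- **MI** is joint-histogram mutual information (64 bins) normalised by
  min(H(o), H(g)) so the stated 0–1 range holds and the result is log-base
  invariant. Raw nats are available via `normalized=False`.
- **PSNR** is the standard `10·log10(max(o)²/MSE)`: the printed alternative
  (20 log max − 20 log MSE) is inconsistent with the reported ~12–16 dB
  regime but remains available behind `printed_form=True`. Identical images
  return a 100 dB cap. The peak is taken from the first argument
  (documented asymmetry).
- **Blur index** uses horizontal first-difference prediction residues
  p(i,j) = x(i,j+1) − x(i,j) and returns the mean squared deviation from
  their per-image median. Calibration on a textured fixture shows the index
  *decreases* monotonically under Gaussian blur; that direction is frozen
  in the tests. The residue definition is the simplest estimator of the
  cited family and is declared rather than assumed.
- **Aggregation**: pairwise metrics average over the full cross-product
  (self-pairs excluded for the original-vs-original reference range); FID's
  reference range comes from comparing developmental-stage subgroups of the
  originals (three contiguous chunks when no stage labels are given); blur
  is per-image (originals: min/max, synthetic groups: mean).

## Psychovisual analysis

Pass answers are excluded from the four confusion counts and tallied
separately by default — the only policy under which each group's four
counts sum exactly to experts × group size; `count_as_generated` is
available since a pass can also be read as an answer. NER weights use the
mean decision time *of the relevant error category within the analysed
group*, not global means. Percent reporting rounds half away from zero
(0.41875 → 42 %).

The statistical battery routes explicitly and logs every decision: Shapiro
per group (constant samples are treated as non-normal), then Bartlett (all
normal) or Levene, then one-way ANOVA + Tukey HSD on the fully parametric
branch or Kruskal–Wallis + Holm-corrected pairwise Mann–Whitney otherwise;
α = 0.05. Groups with n < 3 are excluded with a warning. Identical groups
are reported as p = 1 (scipy's F statistic underflows slightly negative
there and is clamped).

## Metric concordance

"Dimensional reduction" of a metric subset is standardise-then-first-
principal-component (population ddof 0, leading loading forced positive);
a singleton subset is its z-score. Histograms use 16 equal-width bins over
the pooled feature range (widened to 4 bins when any group has < 5 images)
with additive smoothing ε = 10⁻⁶ before the KL divergence; natural log
throughout, so units are nats. Ranking is by |Pearson r| against NER with
|Kendall τ| as tie-break; correlations are computed per group (the
per-image option exists through the inputs). Constant features yield NaN
and sink in the ranking.

## Segmentation stage

Vote-threshold semantics: the default is "validated by ≥ k experts" with
slot capping at the 40 available synthetic slots; an exact-k mode is
provided because the two readings genuinely differ (and published
per-threshold counts are non-monotone, which neither reading fully
explains — the discrepancy is surfaced, not resolved). Whitening is
per-image intensity standardisation rescaled to [0, 255]. The predicted
mask threshold is 0.5 with no morphological post-processing, so scores
reflect the raw predictor.

The default segmenter is a multiscale pixel-feature logistic model: per
pixel, raw intensity, Gaussian-smoothed intensities at σ ∈ {1, 2, 4}, the
corresponding local-contrast channels, and normalised coordinates, fed to
a scikit-learn logistic regression trained on up to 3 000 deterministically
subsampled pixels per image. It is a desk-scale model chosen for speed and
reproducibility behind the same `fit`/`predict` contract any stronger
segmenter (e.g. an encoder–decoder network) would implement; on
high-contrast ellipse fixtures it exceeds 0.8 mean Dice, on generated
organoids (gradient background, rim texture) it reaches ~0.7 — adequate for
harness validation, not a segmentation benchmark. An `OracleSegmenter`
(preloaded ground truth) verifies the harness itself: 40 originals → 40
sessions, mean Dice exactly 1.0, with a hard abort on hold-out leakage.

## Problem sizes

The test suite and `scripts/acceptance.py` run everything at desk scale as
the package's own profile: 32–64 px images, ≤ 100 training epochs, 8–40
images per stage, 40-session leave-one-out with the oracle and an
8-session leave-one-out with the trained segmenter. These sizes were chosen
once as the smallest at which every contract is exercised.

## Known limitations

- Generated organoids are geometric emulations; no claim transfers to real
  acquisitions without re-measuring.
- The AAE is dense, not convolutional, and desk-scale synthesis is blurry;
  the architecture is configurable but the package does not aim to
  reproduce GPU-scale image quality.
- The transport losses operate on flattened intensity distributions; a
  critic-based estimator would be needed for spatially aware Wasserstein
  training.
- The concordance stage's per-group correlations rest on very few points
  (seven groups); treat rankings as exploratory, as intended.
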