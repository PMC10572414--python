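# Methods

## Problem and model

`octaug` segments schisis cavities — fluid-filled, hypo-reflective splitting
spaces inside retinal layers — in 2-D OCT B-scans, and searches automatically
for the data-augmentation policy that best helps that segmentation. There are
two coupled learners:

**Child segmentation model.** An encoder-decoder network `M_ω` (U-Net,
U-Net++, Attention U-Net, or Residual U-Net) maps a 1×H×W grayscale scan to
2×H×W class logits (background / cavity). Training minimizes the hybrid loss

    L = ½·L_CE + ½·L_Dice,
    L_CE   = −(1/N) Σ_pixels Σ_classes p·log q,
    L_Dice = 1 − (2·Σ y·ŷ + α) / (Σ y + Σ ŷ + α),

with one-hot target `p`/`y`, predicted probability `q`/`ŷ` (Dice on the
foreground channel only), and smoothing `α` keeping the loss defined when an
image contains no cavity (`y = ŷ = 0` gives exactly 0). `α` defaults to 1.0;
it only matters near-empty masks, where any O(1) value behaves the same.

**Policy controller.** Augmentation strategies live in a discrete space: 16
image operations (7 geometric, 9 photometric), each with 10 magnitude levels
spanning its printed range and 11 probability levels φ ∈ {0.0, …, 1.0}. A
*sub-strategy* is an ordered pair of operation instances; a *strategy* is
five sub-strategies, so one strategy is 30 categorical decisions. A
single-layer LSTM (100 hidden units, parameters initialized uniformly in
±0.1) emits those decisions autoregressively — operation type (16-way),
magnitude (10-way), probability (11-way), repeated — with two fully
connected prediction layers per vocabulary. Each sampled token is embedded,
summed with a step-type embedding (so the three vocabularies do not
collide), and fed back as the next input.

The search is bilevel: for each sampled strategy `F`, a freshly initialized
child is trained with `F` (per mini-batch, one sub-strategy is drawn
uniformly from `F` and applied to the whole batch), then evaluated on
held-out validation patients; the reward is `R = −L(M_ω, D_valid)`. The
controller is updated by PPO, and after `T` iterations the sub-strategies of
the five highest-reward strategies (ties broken by earlier iteration) are
concatenated into the 25-sub-strategy consolidated policy used for final
training.

## Policy-update details

The printed update rule for this class of controllers is the plain score-
function gradient; the optimizer named alongside it is PPO. We implement
PPO-clip and keep a REINFORCE mode as the analytically checkable limit
(one epoch, no clipping; a unit test matches it against the closed-form
policy gradient on a 2-action bandit).

Choices that the outer description leaves open, all exposed in
`ControllerConfig`:

* **Per-step ratios.** The clipped surrogate uses one probability ratio per
  decision, averaged over the 30 steps. A single joint ratio over 30 steps
  saturates the clip range after one update (we measured clip fractions
  near 1.0), killing the gradient and leaving the policy to drift on
  advantage noise; per-step ratios keep the clip meaningful (clip 0.2,
  3 epochs per update).
* **Baseline.** Advantages are rewards minus an exponential moving average
  of past rewards (decay 0.95), initialized to the first batch mean so the
  first update is entropy-only.
* **Advantage normalization.** Within each update batch, advantages are
  standardized (skipped when the spread is ~0, so a constant-reward batch
  produces no policy movement). Without this, Adam's scale invariance turns
  near-zero advantages into full-size noise steps.
* **Update batch.** One strategy is sampled per search iteration; updates
  run on a sliding window of the last 10 (strategy, reward) pairs.
* **Entropy bonus** weight 1e-5, learning rate 4e-4 (Adam): the study
  protocol values, used at the full horizon T = 1000.

## Scale presets

The full-scale preset mirrors the study protocol: T = 1000 search
iterations, 200 child epochs per iteration, 512×512 inputs, depth-4/base-32
children, Adam 1e-4 with ReduceLROnPlateau (factor 0.5, patience 10), batch
size 8. That is a GPU-cluster workload; every budget is therefore a config
knob, and the package ships a desk preset used throughout the tests:

| knob | full | desk | rationale for desk value |
|---|---|---|---|
| search iterations T | 1000 | 30 | minutes on one CPU core |
| child epochs E | 200 | 30 | enough for the child to fit its 12-image train set |
| child | depth 4, base 32, 512 px | depth 2, base 4, 32 px | ~2 s per child |
| child learning rate | 1e-4 | 1e-3 | scaled to the shorter schedule |
| controller learning rate | 4e-4 | 1e-2 | horizon rescaling ≈ ×(1000/30), so a 30-iteration search makes comparable total policy movement |
| child seeds across iterations | independent | common | see below |

**Common random numbers.** At desk scale the reward difference between two
strategies (~0.03 in hybrid loss) is smaller than the spread induced by
child initialization (~0.1). The desk preset therefore evaluates every
strategy against the same child initialization, data order, and
augmentation stream — the classic paired-comparison variance reduction.
Each child is still freshly initialized per iteration; only the draws are
shared. The full-scale preset keeps independent per-iteration seeds.

Translation magnitudes are calibrated in pixels at the native 512-px width
and scale proportionally when images are resized, so ±150 px at full scale
means ±9 px on a 32-px desk image.

## Augmentation semantics

* Geometric operations (shears, translations, rotation, flips) transform
  image and mask with identical parameters: bilinear resampling for the
  image, nearest-neighbour for the mask followed by re-binarization at 0.5.
  Vacated regions are filled with intensity 0 and background class (OCT
  vitreous is dark).
* Photometric operations transform the image only; the mask is returned
  bit-exact.
* Signed ranges (ShearX/Y ±0.3, TranslateX/Y ±150 px, Rotate ±30°) are
  discretized linearly across the full signed range — level 0 is the
  minimum, level 9 the maximum; no extra sign flip.
* PIL enhancement operations (Color, Contrast, Sharpness, Brightness) carry
  unsigned printed ranges; the enhancement factor is `1 + s·magnitude` with
  `s = ±1` drawn from the seeded stream, the convention of the PIL-based
  auto-augmentation lineage.
* Color is mathematically the identity on a single grayscale channel (a
  saturation blend toward the image's own grayscale rendering). It is kept
  so the operation vocabulary stays at 16.
* Solarize's magnitude is the inversion threshold in [0, 256]; Posterize's
  is the retained bit count, rounded to an integer (levels 0–9 map to bits
  4,4,5,5,6,6,7,7,8,8).
* A serialized policy may carry a `null` magnitude level on a
  magnitude-bearing operation (published policies do); the native value
  then falls back to the range midpoint.

## Data pipeline

Splits are strictly patient-level: both eyes and all 25 scans of a patient
travel together. The nested scheme per fold of the k = 5 cross-validation:
the fold is the test set (20% of patients), 12.5% of the remaining patients
(rounded to the nearest integer) form the augmentation-search validation
set (10% overall), and the rest train the child (70% overall). For the
30-patient default this is exactly 21/3/6 patients.

Accuracy is reported in two variants, because the class-averaged formula
`(1/k)Σ p_jj/g_j` cannot reach the ~0.99 headline values that overall pixel
accuracy `(TP+TN)/N` produces under heavy class imbalance; the record
carries both, with overall pixel accuracy as the headline. Metrics with an
empty denominator score 1.0 when no errors of either kind exist and 0.0
otherwise, and are flagged on the record. Run comparisons use Welch's
two-sided two-sample t-test per metric — an unpaired test with no
equal-variance assumption, appropriate for independent cross-validation
runs; zero-variance-both-sides rows are flagged instead of producing NaN.

## The phantom generator

No public dataset of XLRS OCT volumes exists, so the package ships a
synthetic layered-retina phantom that reproduces the *structure* of the
cohort: 30 patients × 2 eyes × 25 consecutive B-scans (1500 images) by
default. Each eye is a small 3-D scene:

* a bright retinal band with a foveal dip and gentle undulation, stacked
  from six sub-layers with per-eye reflectivity gains;
* 1–4 schisis cavities as 3-D ellipsoids spanning several consecutive
  scans (half-extent ~9 scans along the scan axis), so adjacent masks
  overlap coherently (measured mean adjacent-scan Dice ≈ 0.86) the way the
  annotation protocol for real cavities expects; cavity interiors multiply
  tissue intensity by 0.22, so they are darker than their surroundings in
  every rendered scan;
* correlated multiplicative speckle (gamma multi-look model; strength 0.25
  ≈ 16 looks, smoothed with a σ = 0.8 Gaussian);
* occasional vertical vessel shadows (rate 0.4 per scan, 55% attenuation);
* per-eye brightness offset (±20) and contrast gain (0.8–1.2) emulating
  acquisition variability.

Appearance knobs were chosen once for structural plausibility; none are
printed protocol values. What the phantom does **not** emulate: real
layer-by-layer reflectivity profiles, motion artifacts, vendor-specific
resolution anisotropy, or pathology other than cavities. Tests that pass on
the phantom therefore validate the *pipeline* — mask-consistent
augmentation, leakage-free splitting, reward bookkeeping, the direction of
the augmentation effect — not clinical segmentation accuracy.

The test suite's domain-shift task renders training eyes with no
brightness/contrast jitter and validation eyes with strong jitter
(brightness ±60, contrast 0.4–1.6): a purely photometric shift under which
photometric augmentation measurably helps, mirroring the qualitative
finding that the searched policies favour intensity transforms while
geometric ones are seldom selected.

## Numerical choices

* All computation is float64 numpy on the CPU; every stochastic component
  draws from an explicit `numpy.random.Generator`, and sampling, training
  and updates are bitwise reproducible under a fixed seed.
* Cross-entropy probabilities are clipped to [1e-7, 1−1e-7].
* Max-pool gradients route to the first maximal entry on ties.
* Batch normalization is the default (instance norm is a config knob);
  evaluation mode uses running statistics with momentum 0.1.
* The learning-rate scheduler halves on a plateau of the epoch-mean
  training loss (factor 0.5, patience 10).

## Known limitations

* Desk-scale children barely generalize across phantom patients; the
  directional tests are majority-of-seeds statements under their fixed
  phantom draw, not effect-size claims. Whether a 25-sub-strategy policy
  beats the unaugmented baseline on a *given* draw varies with the
  rendered cohort: the photometric-dominance of the searched policy is
  robust, the end-to-end Dice gain at this scale is not.
* "Top five strategies" is read as top-5 by reward over the whole trace
  (the natural reading; last-5 is the alternative).
* Whether the full-scale protocol warm-starts children across iterations
  is unknown; fresh initialization per iteration matches the bilevel
  objective and is what we implement.
* The SGD settings retained in `SearchConfig` (`sgd_*`) belong to a
  transformer-hybrid baseline outside this package's scope and are unused.
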