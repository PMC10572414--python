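# octaug

Automatic data-augmentation policy search for segmenting schisis cavities
in retinal OCT B-scans.

X-linked juvenile retinoschisis (XLRS) produces fluid-filled splitting
cavities inside the retina. Quantifying their area in OCT cross-sections is
a disease-progression marker, but expert annotation is slow and data is
scarce, so segmentation models lean heavily on data augmentation — and
*which* augmentations help is dataset-specific. `octaug` treats the choice
as a search problem: a recurrent policy controller, trained with
reinforcement learning, searches a discrete space of paired image
transformations for the policy that minimizes a child segmentation model's
validation loss.

The package is for researchers who want a fully inspectable, CPU-runnable
implementation of this kind of bilevel augmentation search: the U-Net
family of child models, the hybrid loss, the metric suite, the patient-level
cross-validation protocol, and a synthetic layered-retina phantom that makes
everything testable without clinical data. The neural substrate is a compact
numpy autograd engine (`octaug.nn`) — no GPU framework required.

## The method

An augmentation *strategy* is `F = {f̃₁, …, f̃₅}`, where each sub-strategy
`f̃ᵢ = o₁(x; μ₁, φ₁) ∘ o₂(x; μ₂, φ₂)` chains two of 16 PIL-style image
operations with discretized magnitude `μ` (10 levels across each
operation's range) and application probability `φ` (11 levels). One
sub-strategy is a choice among `(16·10·11)² ≈ 3.1·10⁶` configurations; five
of them make the search space `(16·10·11)¹⁰ > 10³²`. Masks are transformed
together with their images for geometric operations and left untouched for
photometric ones.

The search is the bilevel problem

    F* = argmin_F  L( argmin_ω L(M_ω, F(D_train)),  D_valid ),
    D_train ∩ D_valid = ∅  (patient level),

attacked with policy gradients: an LSTM controller (100 hidden units) emits
a strategy as 30 categorical decisions, a freshly initialized child U-Net
is trained under it (each mini-batch augmented by one uniformly drawn
sub-strategy), and the reward `R = −L(M_ω, D_valid)` on the hybrid loss
`L = ½ L_CE + ½ L_Dice` updates the controller via PPO. After `T`
iterations, the sub-strategies of the five best strategies are concatenated
into a 25-sub-strategy consolidated policy used for final, five-fold
patient-level cross-validated training. `policies/unetpp_consolidated.json`
ships a published consolidated policy for U-Net++ in the serialized format.

See `docs/methods.md` for the full model description, parameter defaults,
desk-vs-full-scale presets, and known limitations.

## Worked example

A desk-scale run of the whole pipeline (synthetic data, 30 search
iterations, 32-px children) from the shell:

```bash
octaug synth --out scratch/demo --patients 6 --eyes 1 --scans 4 --size 32 --seed 1
# wrote 24 scans; manifest: scratch/demo/manifest.csv

octaug split --manifest scratch/demo/manifest.csv --k 3 --seed 0 --out scratch/plan.json
# 3 folds; fold 0: 3 train / 1 valid / 2 test patients

octaug search --manifest scratch/demo/manifest.csv --plan scratch/plan.json \
              --fold 0 --out-dir scratch/run --seed 0
# 30 iterations; best reward -0.6999; consolidated policy: 25 sub-strategies
```

`scratch/run/` then contains `trace.csv` (per-iteration strategy, reward,
validation loss), `consolidated_policy.json` (the 25 merged sub-strategies
of the five best iterations), and `resolved_config.yaml`. The reward is the
negative validation hybrid loss, so "best reward −0.6999" means the best
strategy's child reached validation loss 0.6999; the consolidated policy is
what you pass to `octaug train --policy …` for final cross-validated
training, and `octaug compare` turns two runs' per-fold metric CSVs into a
per-metric Welch-t-test report.

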