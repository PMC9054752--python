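# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limits of what the test-bed can show.

## Decoding model

NNoD ("Neural Networks on Dictionaries") is a family of fully connected
networks on dictionary loadings `x ∈ ℝ^p`. With no hidden layer the score is
`f_θ(x) = Wx + b` (multi-label logistic regression); with 1–3 hidden layers
each affine map is followed by the identity or the rectifier
`z ↦ max(z, 0)`. Output coupling is either

* **binary**: per-label Bernoulli, `ŷ = σ(f_θ(x))`, loss
  `−Σ_l [y^l log ŷ^l + (1−y^l) log(1−ŷ^l)] + R(θ)`; or
* **multinomial**: `ŷ = softmax(f_θ(x))`, loss
  `−Σ_l (y^l / Σ_k y^k) log ŷ^l + R(θ)` — the target is normalized by the
  label sum, so multi-label rows become a distribution over their labels
  rather than replicated one-hot examples.

`R(θ)` is an elastic net over the weight matrices only (biases excluded):
`R = λ₁ Σ|W| + λ₂ Σ W²`. One `(λ₁, λ₂, dropout)` triple applies to every
layer. Dropout uses inverted scaling on the input and hidden activations
during training, so evaluation needs no rescaling.

Key parameters (defaults chosen once, exposed in `ModelConfig`):

| parameter | default | rationale |
|---|---|---|
| hidden layers × width | 1 × 300, rectifier | the selected configuration of the study design this package implements |
| dropout rate | 0.2 | idem |
| λ₁ = λ₂ | 0.001 | idem |
| optimizer | Adam, lr 1e-3, batch 256, 100 epochs | no optimizer is prescribed by the design; Adam is robust across the fixture scales used here and everything is config-exposed |
| initialization | uniform ± √(1/fan_in), seeded | standard fan-in scaling; full determinism given the seed |

Probabilities are clamped to `[1e-7, 1 − 1e-7]` inside the losses; the
softmax subtracts the row maximum for stability; the sigmoid is computed in
the numerically safe branch-wise form. Analytic gradients (including the
`λ₁ sign(W) + 2λ₂ W` penalty term and the dropout masks) are verified
against central finite differences for all 16 architecture/loss
combinations; the comparison uses a relative-or-absolute hybrid with an
absolute floor of 1e-4 because central-difference roundoff (~1e-10) would
otherwise dominate near-zero gradient entries.

Grid search trains every candidate configuration and selects by validation
macro AUC, ties broken toward the earlier candidate.

## Signal representation

Projection is per-map ordinary least squares onto each dictionary, solved by
`gelsd` (SVD), which yields the minimum-norm solution when a dictionary is
rank deficient. Loadings are not rescaled or standardized before modeling;
a stack concatenates resolutions in descending component count
(1024 ‖ 512 ‖ 128 → 1664 features) — the order is irrelevant to the model
but fixed for serialization stability. The positive part clips loadings at
zero; because components are non-negative this approximates keeping only the
positive part of the map.

## Labeling

Matching is exact at word boundaries, case-insensitive, after whitespace
normalization; annotation fields are joined with a hard `" ; "` separator so
phrases cannot span fields. Registered synonyms match like canonical names.
Hypernym closure is computed through an ancestry matrix, so it is idempotent
and never removes a positive. Curation rules rewrite tokens first, then
match, then fire collection rules, then merge synonym columns (logical OR
into the survivor); they are intended for training collections only — the
pipeline applies raw extraction + closure to held-out collections so
reported metrics are not biased by hand-tuned rules. Vocabulary pruning
iterates to a fixed point: drop all concepts with fewer than `min_count`
(default 10) positives, then repeatedly drop the rarer member of the
most-correlated pair with |phi| > `max_abs_corr` (default 0.95; ties drop
the later column). Constant columns have undefined phi and are treated as
uncorrelated.

## Evaluation

Per-label AUC uses midrank statistics (ties count ½), which equals the
pair-probability definition; labels missing a class in the test split are
excluded with a reason rather than scored 0.5, keeping the macro average
meaningful. WR@k ranks each map's scores with boundary ties broken by
ascending label index; its denominator is the count of the label's positive
test maps, the only reading that keeps the metric in [0, 1]. Splits hold
out whole collections; the evaluable vocabulary is restricted to concepts
positive on both sides of the split.

## Synthetic repository

The generator emulates what the analysis must survive, at desk scale:

* **Forward model.** `voxels = Σ_c effect·Bᵀs_c − u·Bᵀc_coll + ε`. Each
  concept owns a fixed sparse non-negative loading signature `s_c` (4
  components of a 256-component generating dictionary); 1–3 concepts are
  active per map; `c_coll` is a sparse non-negative per-collection
  control-condition pattern (~10% of components, half-normal amplitudes of
  scale `baseline_shift_sd`) subtracted with per-map intensity
  `u ~ Uniform(0.5, 1.5)`; `ε` is i.i.d. Gaussian. The subtractive control
  reproduces the core confound of contrast maps — each study subtracts "more
  or less" of a different control response — and is what the positive-part
  representation mitigates. An earlier design (a constant signed additive
  shift per collection) was discarded: a shift constant within a collection
  is invisible to within-collection ranking metrics and spans too few
  directions to harm a linear model, so it produces no representation
  ordering at all.
* **Dictionaries.** Components are contiguous blobs grown from random
  centers with Gaussian radial profiles (probabilistic-atlas style), support
  ≈ `(1−sparsity)·V` voxels; while growing, already-claimed voxels are
  entered with probability `overlap` (disjoint supports at 0). Blob
  geometry matters: with scattered random supports, OLS loadings of a
  non-negative signal come out heavily signed and clipping destroys signal
  instead of suppressing the control.
* **Ontology.** A hypernym forest whose names compose (child = modifier +
  parent name), so word-boundary containment between canonical names
  coincides with ancestry — this is what makes noiseless extraction plus
  closure equal the generator truth exactly. Synonyms are abbreviations
  ("working memory" → "wm").
* **Map types.** t-maps are z-maps scaled by Uniform(0.8, 1.25); beta-maps
  add Student-t(3) noise — the exact real-world distributions are not
  modeled, only the mixture's nuisance character.
* **Annotations.** Every truth label's name is written into the contrast
  definition, then independently corrupted: synonym substitution, vowel
  dropping, adjacent-character typo, omission (5% each by default).
* **Contaminants.** Thresholding (zero the 60% smallest |values|), low
  coverage (keep a random 35% of voxels), wrong modality (metadata flag);
  5% each by default, independent.

Two named fixtures freeze the study conditions:

* `standard_fixture` — 3 collections × 170 maps, 20 concepts, 1200-voxel
  grid, effect 3.0 vs noise 0.5 (high SNR), control scale 2.0. Used for the
  end-to-end recovery check (leave-one-collection-out macro AUC with the
  reference model) and the labeling-correctness check.
* `representation_fixture` — 12 collections × 60 maps on a 4096-voxel grid,
  noise 2.0, control scale 4.0, no annotation noise or contaminants. Used
  for the representation-comparison grid: many small collections make the
  control vary across training, the larger grid keeps any single dictionary
  from spanning the signal, and the higher noise keeps AUC off the ceiling —
  with only 3 big collections every cell saturates near 0.99 and the grid
  ordering is noise.

What the generator does **not** emulate: spatial smoothness and anatomical
structure of real activations, inter-subject variability, scanner/pipeline
effects, realistic annotation language (only canonical names plus simple
corruptions), and the heavy class imbalance of real repositories. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that its qualitative mechanisms (positive-part robustness, multi-resolution
stacking, nonlinearity benefits) operate as designed — not that real-data
decoding will reach the same scores.

## Statistical controls

The permutation control retrains the reference model on row-permuted
training labels and scores the untouched test labels. A single permutation
draw of the macro AUC null has a standard deviation around 0.03 on the
standard fixture (20 closure-correlated labels, ~170 test maps), so the
control reports the null center as the mean over three independent
permutations, expected at 0.5.

The nonlinearity check uses an exclusive-or fixture (concept active iff
exactly one of two components is high): linear models are near chance by
construction while one rectifier hidden layer separates it.

## Known limitations

* The per-map OLS projection ignores any whitening or joint fitting across
  maps; rank-deficient dictionaries fall back to minimum-norm solutions.
* Duplicate detection is exact (content hash of standardized in-mask
  values); near-duplicates differing by resampling jitter survive.
* Beta-map quality control uses a fixed absolute cap (default 500) rather
  than a data-dependent percentile, trading a little realism for idempotent
  filtering.
* The encoding regression includes an intercept and the full concept matrix;
  with strongly collinear (e.g. fully closure-determined) label columns it
  falls back to a flagged minimum-norm fit.
* Multinomial training requires every row to carry at least one positive
  label; unlabeled maps must be dropped before fitting.
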