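# Methods

## Problem setting

Let `X⁽ᵛ⁾ ∈ R^{n×p_v}`, v = 1..V, be feature matrices for the same n
cells across V ≥ 2 modalities, with optional per-cell group labels in
{1..K}, batch identifiers, and 2-D spatial coordinates.  The package
jointly learns (i) a group assignment per cell — unsupervised
clustering, or supervised classification for annotation transfer — and
(ii) cross-modal predictors x̃⁽ᵛ¹→ᵛ²⁾ = Dec⁽ᵛ²⁾(Enc⁽ᵛ¹⁾(x⁽ᵛ¹⁾)), both
through one shared latent space.

## Architecture

Per modality: encoder, decoder, discriminator, all multilayer
perceptrons.  Defaults: two hidden layers of width 128 with batch
normalization and ReLU; latent dimension d = 32 (identical across
modalities, a structural requirement for fusion); decoders mirror the
encoders and end linearly, except for binarized modalities, which end
in a sigmoid so outputs are probabilities; discriminators have no
batch norm and one linear output score (least-squares adversarial
targets, no sigmoid).  The head applies one 64-unit hidden layer to the
fused code and a bias-free linear map to K softmax logits (the soft
assignment is a bare inner-product softmax).  Fusion weights η live on
the simplex by construction — they are the softmax of V free logits —
so no projection or clipping is ever needed.

These widths and depths are implementation defaults, exposed in
`ModelConfig`; the method does not depend on them.

## Losses

* **Clustering** (unsupervised group loss, three parts).  With
  similarity kernel `s_ij = exp(−‖h_i−h_j‖²/2σ²)` on the head's hidden
  representation h: part 1 is the mean over group pairs k<l of the
  kernel-weighted correlation `α̃ₖᵀSα̃ₗ/√(α̃ₖᵀSα̃ₖ·α̃ₗᵀSα̃ₗ)` of the
  per-group assignment vectors; part 2 has the same form with
  `m_k(i) = exp(−‖α_i−e_k‖²)`, pulling assignments toward distinct
  simplex corners; part 3 is `Σₖ ᾱₖ log ᾱₖ`, minimized at −log K by the
  uniform mean assignment, which blocks cluster-count collapse.
* **Prediction.**  Per-cell Euclidean norms (not squares) of the
  within-modality and cross-modality residuals, averaged over cells and
  modalities / unordered pairs (v₁ < v₂); binarized modalities
  contribute mean binary cross-entropy instead.
* **Adversarial.**  Least-squares: generator drives Dis(x̃) toward 1;
  discriminator drives Dis(x̃) toward 0 and Dis(x) toward 1.
* **Contrastive.**  Cosine similarities between per-cell codes; the
  positive is the cell's own cross-modal similarity, negatives are
  sampled (default 256) from similarities — over all ordered modality
  pairs, including within-modality — to cells whose assigned group
  differs.  The positive is *not* added to the denominator, so
  individual terms may be negative; an `include_positive` toggle
  restores the standard InfoNCE form.  In supervised mode negatives use
  the true labels (predictions are untrustworthy early in training).
  Scaled by δ (default 1), temperature τ = 0.1.
* **Classification** (supervised group loss).  Cross-entropy weighted
  by g_i = n_{k(i)}/n — the frequency of the cell's own class, which
  up-weights common classes; an inverse-frequency option is available
  and off by default.

Composites: group loss = sum of the three clustering parts (or the
classification loss); prediction-step loss = within + cross +
generator + contrastive, all unweighted.

## Training procedure

Per minibatch (default 256, last partial batch kept, singleton batches
skipped because several terms are batch statistics): the group step
runs c·V times (c = 1) updating encoders, η, and the head; then the
discriminators update on the discriminator loss with detached
reconstructions; then encoders and decoders update on the
prediction-step composite.  Decoders are forward-only in the group
step.  Three disjoint Adam optimizers (lr 1e-3, global-norm gradient
clipping at 10); fixed epoch count, no early stopping; every loss is
checked finite each step and a NaN aborts with epoch/step diagnostics.
Everything runs on a hand-rolled float64 reverse-mode autodiff engine
over numpy, so runs are exactly reproducible on one CPU thread given
the seed.

### Numerical choices

* σ is set per batch as `sigma_rel ×` the median pairwise distance of
  h.  `sigma_rel` defaults to **0.3**: at the conventional 0.15 the
  kernel is local enough that roughly one initialization in five
  settles into a confidently wrong balanced partition whose final loss
  is indistinguishable from a correct run (so restart selection cannot
  repair it); 0.3 removed these collapses across seeds without
  degrading converged solutions.
* ε = 1e-9 guards all divisions and logarithms; prediction norms carry
  1e-12 inside the square root so the gradient at perfect
  reconstruction is finite.
* Kernel and mean-assignment statistics, and the negative-sampling
  pool, are evaluated per minibatch — a deliberate stochastic
  approximation of the full-data sums, which scale as n².
* argmax ties in group assignment break to the lowest index.
* Batch-norm uses batch statistics in training and running averages at
  inference; inference is therefore deterministic, and the attribution
  machinery only ever sees the inference-mode (affine) form.

## Ablation variants

`no_prediction_task` skips the prediction step entirely;
`no_group_task` skips the group step; `no_discriminator` is the
dual-autoencoder baseline — two vanilla autoencoders trained on
within-modality reconstruction only, with no adversarial game, no
contrastive alignment, and no group coupling, whose cross-modal route
is still evaluated through the (now unaligned) latent spaces.

## Shapley attribution

`shapley_exhaustive` implements the exact subset-enumeration value:
the value of a feature subset S is the mean model output over the
background rows with S replaced by the explained point, and φ_j is the
factorial-weighted average of marginal contributions (feasible to ~15
features).  `deep_shap` propagates per-layer multipliers: linear layers
and inference-mode batch norm propagate exactly; elementwise
nonlinearities use the rescale rule Δout/Δin per background reference,
falling back to the local derivative when |Δin| < 1e-9; attributions
are multiplier × (input − reference), averaged over references.  This
composition preserves the local-accuracy identity Σ_j φ_j = f(x) −
mean_background f exactly for supported chains, and coincides with the
oracle on linear networks.

Group→feature relevance attributes each group's assignment unit — on
the pre-softmax logit by default (the probability-scale option
linearizes the softmax at the input/reference midpoint and is provided
for completeness) — over the cells assigned to that group, averaging
|φ| per feature; the fused sum is additive across modality branches, so
multipliers distribute to each encoder exactly.  Default background:
per-group mean profiles (the large-data choice); any row matrix can be
supplied.  Cross-modal feature→feature relevance runs through the
source encoder → target decoder chain for the cells of one group.
Rankings always use raw mean |φ|; min-max normalization is display
only.  The robustness protocol splits cells into k folds, takes each
fold as calculation data and the remaining k−1 folds as the reference
set (optionally subsampled), and counts how often each feature enters
the top-n; `retrain_per_fold` additionally retrains on the k−1 folds.

## Evaluation metrics

ARI (pair-counting contingency form), R² against the constant-mean
baseline, Pearson's r as a centered cosine, and pairwise-counting AUC
whose strict indicator counts tied pairs as 0 (a `ties="half"` option
gives the conventional 0.5).  Both flattened-overall and per-feature
variants are reported for prediction matrices, since either convention
appears in practice.  All four agree with the scikit-learn reference
implementations to 1e-10 on random instances (tie-free for AUC).

## Spatial module

The niche modality replaces cell i's features by
`Σ_j w_ij x_j` over its J nearest spatial neighbors (Euclidean, self
excluded, deterministic index tie-break), with w_ij ∝ 1/distance
normalized per cell; a zero-distance neighbor takes the full weight
(shared equally if several).  J defaults to 10.  Label refinement is a
single synchronous pass assigning each spot the strict-majority
(> 50%) label of its n nearest spots (default 35), otherwise leaving it
unchanged.

## Synthetic study designs

The generator draws K group centers on randomly rotated orthogonal
directions scaled so every pair of centers is exactly `separation`
apart, samples each cell's latent state as center + N(0, I), and
observes each modality through its own random linear map plus Gaussian
noise — shared group structure seen through different feature spaces,
which is the property the method exploits.  Presets: a four-modality
design (500 cells, 4 groups, 100 features each, DNA / pre-mRNA / mRNA /
protein-like) and a paired design (1000 cells, 10 groups, 500 features)
where one modality is corrupted by Bernoulli dropout with keep
probability `decay` ∈ (0,1].  Batch structure adds one constant offset
vector of Euclidean magnitude `shift` per (batch, modality); spatial
layouts place cells on a grid with contiguous label bands.
`plant_markers` adds a fixed effect to chosen features within one
group's cells and records the ground truth for recovery protocols.

Study conditions used by the test-suite protocols, fixed once: the
recovery design is n = 600, K = 3, V = 2, 40 features per modality,
separation 6, noise SD 0.5, 50 training epochs; the multi-task
comparison runs on the four-modality preset (30 epochs), where the
modalities are individually weak enough for the task coupling to
matter; planted markers use effect 6.0, at which every planted feature
is among its group's largest univariate contrasts (the generator's
latent maps give *all* features some natural group contrast, so small
effects do not make a feature a marker in any meaningful sense — the
premise is asserted before the attribution check).

What these designs do not emulate: count noise and zero inflation
beyond Bernoulli dropout, nonlinear feature interactions, regulatory
kinetics, imbalanced rare populations, or realistic batch effects
(offsets only).  Passing tests show the machinery — optimization,
adaptive weighting, attribution — behaves as designed under shared
linear-Gaussian group structure; they do not certify performance on
real multi-omics data.

## Known limitations

* Desk-scale by design: dense numpy matrices and an n_b × n_b kernel
  per minibatch; no GPU or sparse path.
* The clustering objective is self-referential (the kernel lives on a
  learned representation); rare confident misclusterings remain
  possible at unlucky initializations, and the loss value does not
  flag them.
* Deep SHAP supports dense / ReLU / sigmoid / inference-batch-norm /
  scaling chains only; unsupported layers raise by name.
* K must be supplied in unsupervised mode; there is no automatic model
  selection.
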