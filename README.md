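# unitednet

Explainable multi-task learning for multi-modality single-cell data.

Modern assays measure several high-dimensional modalities from the same
cells — gene expression together with DNA accessibility, protein
abundance, electrophysiology, morphology, or the expression of a cell's
spatial neighborhood.  Two analyses are usually wanted at once:
**joint group identification** (which cell type or tissue region is
each cell, using all modalities together) and **cross-modal
prediction** (what would modality B look like given modality A).  This
package trains one network for both tasks and then *dissects* the
trained network with Shapley-value attribution, so that group→feature
and cross-modal feature→feature relevance can be read off
quantitatively, with cell-type specificity.

It is written for computational biologists who want a desk-scale,
dependency-light (numpy/scipy/pandas/scikit-learn/anndata)
implementation with exact, testable semantics for every loss and every
attribution rule.

## Model

Each modality `v` has an encoder producing a code `z⁽ᵛ⁾ᵢ ∈ Rᵈ`, a
decoder mapping codes back to features, and a discriminator.  The codes
are fused by trainable simplex weights,

    zᵢ = Σᵥ ηᵥ z⁽ᵛ⁾ᵢ ,   ηᵥ ≥ 0, Σᵥ ηᵥ = 1,

and a two-layer head yields soft group assignments
`αᵢ = softmax(W·layer₁(zᵢ))` over K groups.  Training alternates two
steps per minibatch:

* **group identification** — encoders, η, and the head descend either a
  three-part divergence clustering loss (kernel decorrelation of the
  per-group assignment vectors, simplex-corner compactness, and the
  negative entropy of the mean assignment, which is −log K at its
  uniform optimum) or, in supervised mode, a frequency-weighted
  cross-entropy;
* **prediction** — discriminators descend a least-squares adversarial
  loss, then encoders and decoders descend the sum of within-/
  cross-modality reconstruction norms (binary cross-entropy for
  binarized modalities), the generator loss, and a contrastive loss
  that aligns the same cell's codes across modalities against sampled
  negatives from other predicted groups.

Because η is trained, noisier modalities receive smaller fusion weights
automatically.  After training, a layer-wise Shapley estimator
(DeepLIFT-style multipliers: exact through linear and inference-mode
batch-norm layers, rescale rule through nonlinearities) attributes each
group's assignment unit to every input feature, and each cross-modally
predicted feature to the source modality's features.  An exhaustive
subset-enumeration oracle is included and the two provably agree on
linear networks.

## Worked example

```python
import numpy as np
from unitednet import (GeneratorSpec, ModelConfig, simulate_multimodal, train,
                       infer_groups, predict_cross_modal, ari, group_feature_relevance)

spec = GeneratorSpec(n_cells=600, n_groups=3, n_modalities=2,
                     n_features=(40, 40), separation=6.0, noise_sd=0.5, seed=7)
data = simulate_multimodal(spec)

config = ModelConfig(n_groups=3, epochs=50, seed=0)
model = train(data, config)

labels, alpha = infer_groups(model, data)
print(f"ARI vs ground truth: {ari(labels, data.labels):.3f}")
print(f"fusion weights eta:  {np.round(model.eta, 3)}")

pred = predict_cross_modal(model, data, "mod1", "mod2")
print(f"cross-modal R2 (mod1 -> mod2): {pred.metrics['overall']:.3f}")

relevance = group_feature_relevance(model, data, n_top=5)
print("top features for group 1 / mod1:", relevance.top_features(1, "mod1"))
```

prints

```
ARI vs ground truth: 0.960
fusion weights eta:  [0.516 0.484]
cross-modal R2 (mod1 -> mod2): 0.820
top features for group 1 / mod1: ['mod1_f15', 'mod1_f13', 'mod1_f20', 'mod1_f8', 'mod1_f34']
```

ARI 0.960 means the unsupervised grouping essentially recovers the three
simulated cell types; R² 0.820 means 82% of modality-2 variance is
predicted from modality 1 alone; the near-equal η reflects two equally
informative modalities; the listed features are the ones whose Shapley
relevance for group 1 is largest.

A command-line interface mirrors the library
(`unitednet simulate|preprocess|convert|train|predict|transfer|explain|niche|evaluate|run`);
`unitednet run --config cfg.yaml --out dir/` executes the whole pipeline
and writes a reproducibility manifest.  Data formats: dense CSV/TSV
(cells × features, first column = cell id), MatrixMarket `.mtx` with
`<stem>_barcodes.tsv` / `<stem>_features.tsv` sidecars, or one `.h5ad`
per modality (matrix in `X`).

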