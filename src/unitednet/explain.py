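"""Shapley-value dissection of a trained model.

Two estimators are provided.  :func:`shapley_exhaustive` enumerates all
feature subsets and is exact (the oracle; feasible up to ~15 features).
:func:`deep_shap` propagates DeepLIFT-style multipliers layer by layer —
exact linear propagation through dense and inference-mode batch-norm
layers, the rescale rule ``(f(x) − f(x̄)) / (x − x̄)`` for elementwise
nonlinearities — and averages attributions over the background
references.  On purely linear chains the two coincide; on supported
nonlinear chains the layer-wise estimate retains the local-accuracy
identity Σ_j φ_j = f(x) − mean_background f per row.

The relevance protocols mirror how a trained model is dissected in
practice: group→feature relevance attributes each group's soft
-assignment unit (on the pre-softmax logit scale by default) to every
input feature of every modality; cross-modal feature→feature relevance
attributes a target modality's predicted features to the source
modality's inputs through the encode→decode chain; robustness counts
how often top-ranked features persist across cross-validation folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from .data import MultiModalDataset, split_folds
from .network import ModelConfig, UnitedNetModel
from .nn import BatchNorm, Dense, Layer, ReLU, Scale, Sequential, Sigmoid
from .training import infer_groups, train

logger = logging.getLogger(__name__)

__all__ = [
    "AttributionResult",
    "RelevanceTable",
    "shapley_exhaustive",
    "deep_shap",
    "group_feature_relevance",
    "cross_modal_feature_relevance",
    "relevance_robustness",
    "marker_predictability_check",
]

_SUPPORTED_LAYERS = (Dense, ReLU, Sigmoid, BatchNorm, Scale)


@dataclass
class AttributionResult:
    phi: np.ndarray  # (n_calc, p_input)
    target: str
    background: str


@dataclass
class RelevanceTable:
    """Tidy relevance scores: one row per (group, modality, feature)."""

    table: pd.DataFrame
    n_top: int | None = None

    def top_features(self, group, modality, n: int | None = None) -> list[str]:
        n = n or self.n_top
        sub = self.table[
            (self.table["group"] == group) & (self.table["modality"] == modality)
        ].sort_values("rank")
        return sub["feature"].head(n).tolist()


# ------------------------------------------------------------------ oracle


def shapley_exhaustive(
    f, x: np.ndarray, background: np.ndarray, max_features: int = 15
) -> np.ndarray:
    """Exact Shapley values of ``f`` at a single point ``x``.

    ``f`` maps an (m, Q) matrix to m outputs.  The value function of a
    subset S is the mean of ``f`` over the background rows with the
    features in S replaced by ``x``.  Enumerates all 2^Q subsets.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    Q = x.size
    if Q > max_features:
        raise ValueError(
            f"{Q} features would need 2^{Q} subset evaluations; "
            "use deep_shap for larger inputs"
        )
    n_bg = background.shape[0]
    # value of every subset mask
    values = np.empty(2**Q)
    for mask in range(2**Q):
        members = [j for j in range(Q) if mask >> j & 1]
        comp = background.copy()
        comp[:, members] = x[members]
        values[mask] = float(np.mean(f(comp)))
    phi = np.zeros(Q)
    fact = [factorial(i) for i in range(Q + 1)]
    for j in range(Q):
        for mask in range(2**Q):
            if mask >> j & 1:
                continue
            s = bin(mask).count("1")
            w = fact[s] * fact[Q - s - 1] / fact[Q]
            phi[j] += w * (values[mask | (1 << j)] - values[mask])
    return phi


# --------------------------------------------------------------- deep shap


def _flatten_chain(layers) -> list[Layer]:
    flat: list[Layer] = []
    stack = list(layers)
    while stack:
        layer = stack.pop(0)
        if isinstance(layer, Sequential):
            stack = list(layer.layers) + stack
            continue
        if not isinstance(layer, _SUPPORTED_LAYERS):
            raise ValueError(
                f"unsupported layer type for layer-wise attribution: "
                f"{type(layer).__name__}"
            )
        flat.append(layer)
    return flat


def _chain_phi(
    layers: list[Layer], x: np.ndarray, ref: np.ndarray, unit: int
) -> np.ndarray:
    """Multiplier backpropagation for one reference row; returns
    (n, p) attributions for one output unit."""
    acts_x = [x]
    acts_r = [ref]
    for layer in layers:
        acts_x.append(layer.np_forward(acts_x[-1]))
        acts_r.append(layer.np_forward(acts_r[-1]))
    out_dim = acts_x[-1].shape[1]
    m = np.zeros((x.shape[0], out_dim))
    m[:, unit] = 1.0
    for layer, a_x, a_r in zip(reversed(layers), acts_x[-2::-1], acts_r[-2::-1]):
        m = layer.multipliers(m, a_x, a_r)
    return m * (x - ref)


def deep_shap(
    layers,
    inputs: np.ndarray,
    background: np.ndarray,
    unit: int = 0,
    target: str = "output",
) -> AttributionResult:
    """Layer-wise Shapley estimate for one output unit of a chain of
    supported layers, averaged over the background references."""
    flat = _flatten_chain(layers if isinstance(layers, (list, tuple)) else [layers])
    inputs = np.atleast_2d(np.asarray(inputs, dtype=np.float64))
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    if inputs.shape[1] != background.shape[1]:
        raise ValueError("calculation and background data must share features")
    phi = np.zeros_like(inputs)
    for ref_row in background:
        ref = np.broadcast_to(ref_row, inputs.shape)
        phi += _chain_phi(flat, inputs, ref, unit)
    phi /= background.shape[0]
    return AttributionResult(
        phi=phi,
        target=target,
        background=f"{background.shape[0]} reference rows",
    )


# --------------------------------------------------- model-specific chains


class _FusionHead(Layer):
    """Concatenated-input view of encoders → η-weighted sum → head.

    The input is the horizontal concatenation of all modality feature
    blocks; each block flows through its encoder scaled by η_v, the sums
    feed the head.  The additive fusion lets multipliers from the head
    distribute to each branch independently.
    """

    def __init__(self, model: UnitedNetModel, logit_target: bool = True):
        self.branches = [
            _flatten_chain([model.encoders[v], Scale(model.eta[v])])
            for v in range(model.n_modalities)
        ]
        self.dims = model.input_dims
        self.offsets = np.cumsum([0] + list(self.dims))
        head_layers = [model.head1, model.head2]
        self.head = _flatten_chain(head_layers)
        self.logit_target = logit_target
        self.model = model

    def _blocks(self, x):
        return [
            x[:, lo:hi] for lo, hi in zip(self.offsets[:-1], self.offsets[1:])
        ]

    def np_forward(self, x):
        fused = sum(
            _np_chain(branch, block)
            for branch, block in zip(self.branches, self._blocks(x))
        )
        out = _np_chain(self.head, fused)
        if not self.logit_target:
            e = np.exp(out - out.max(axis=1, keepdims=True))
            out = e / e.sum(axis=1, keepdims=True)
        return out

    def phi(self, x: np.ndarray, ref: np.ndarray, unit: int) -> np.ndarray:
        fused_x = sum(
            _np_chain(b, blk) for b, blk in zip(self.branches, self._blocks(x))
        )
        fused_r = sum(
            _np_chain(b, blk) for b, blk in zip(self.branches, self._blocks(ref))
        )
        # head multipliers
        acts_x = [fused_x]
        acts_r = [fused_r]
        for layer in self.head:
            acts_x.append(layer.np_forward(acts_x[-1]))
            acts_r.append(layer.np_forward(acts_r[-1]))
        out_dim = acts_x[-1].shape[1]
        m = np.zeros((x.shape[0], out_dim))
        if self.logit_target:
            m[:, unit] = 1.0
        else:
            # softmax linearized at the input/reference midpoint
            mid = 0.5 * (acts_x[-1] + acts_r[-1])
            e = np.exp(mid - mid.max(axis=1, keepdims=True))
            p = e / e.sum(axis=1, keepdims=True)
            m = -p[:, [unit]] * p
            m[:, unit] += p[:, unit]
        for layer, a_x, a_r in zip(
            reversed(self.head), acts_x[-2::-1], acts_r[-2::-1]
        ):
            m = layer.multipliers(m, a_x, a_r)
        # distribute into branches (fusion is additive)
        phi = np.zeros_like(x)
        for branch, lo, hi in zip(self.branches, self.offsets[:-1], self.offsets[1:]):
            bx, br = x[:, lo:hi], ref[:, lo:hi]
            b_ax, b_ar = [bx], [br]
            for layer in branch:
                b_ax.append(layer.np_forward(b_ax[-1]))
                b_ar.append(layer.np_forward(b_ar[-1]))
            mb = m
            for layer, a_x, a_r in zip(
                reversed(branch), b_ax[-2::-1], b_ar[-2::-1]
            ):
                mb = layer.multipliers(mb, a_x, a_r)
            phi[:, lo:hi] = mb * (bx - br)
        return phi


def _np_chain(layers: list[Layer], x: np.ndarray) -> np.ndarray:
    for layer in layers:
        x = layer.np_forward(x)
    return x


def _concat_features(dataset: MultiModalDataset) -> np.ndarray:
    return np.concatenate([m.values for m in dataset.modalities], axis=1)


def _group_backgrounds(
    dataset: MultiModalDataset, groups: np.ndarray
) -> np.ndarray:
    """Per-group mean profiles of the concatenated features."""
    X = _concat_features(dataset)
    return np.stack([X[groups == g].mean(axis=0) for g in np.unique(groups)])


def group_feature_relevance(
    model: UnitedNetModel,
    dataset: MultiModalDataset,
    n_top: int = 7,
    groups: np.ndarray | None = None,
    background: np.ndarray | None = None,
    logit_target: bool = True,
    max_cells_per_group: int | None = None,
    seed: int = 0,
) -> RelevanceTable:
    """Mean |Shapley value| of every input feature for each group's
    soft-assignment unit, over the cells assigned to that group.

    Background defaults to the per-group mean profiles.  Rankings use
    the raw mean |φ| per modality; the min-max normalized column is for
    display only.
    """
    if groups is None:
        groups, _ = infer_groups(model, dataset)
    X = _concat_features(dataset)
    if background is None:
        background = _group_backgrounds(dataset, groups)
    chain = _FusionHead(model, logit_target=logit_target)
    rows = []
    rng = np.random.default_rng(seed)
    for g in np.unique(groups):
        members = np.flatnonzero(groups == g)
        if members.size == 0:
            logger.warning("group %s is empty; skipped", g)
            continue
        if max_cells_per_group and members.size > max_cells_per_group:
            members = rng.choice(members, size=max_cells_per_group, replace=False)
        calc = X[members]
        phi = np.zeros_like(calc)
        for ref_row in background:
            ref = np.broadcast_to(ref_row, calc.shape)
            phi += chain.phi(calc, ref, unit=int(g) - 1)
        phi = np.abs(phi / background.shape[0]).mean(axis=0)
        for v, m in enumerate(dataset.modalities):
            lo, hi = chain.offsets[v], chain.offsets[v + 1]
            scores = phi[lo:hi]
            lo_s, hi_s = scores.min(), scores.max()
            normed = (
                (scores - lo_s) / (hi_s - lo_s) if hi_s > lo_s else np.zeros_like(scores)
            )
            order = np.argsort(-scores, kind="stable")
            rank = np.empty_like(order)
            rank[order] = np.arange(1, scores.size + 1)
            for j, name in enumerate(m.feature_names):
                rows.append(
                    {
                        "group": int(g),
                        "modality": m.name,
                        "feature": name,
                        "score": scores[j],
                        "normalized": normed[j],
                        "rank": int(rank[j]),
                    }
                )
    return RelevanceTable(table=pd.DataFrame(rows), n_top=n_top)


def cross_modal_feature_relevance(
    model: UnitedNetModel,
    dataset: MultiModalDataset,
    group: int,
    source_modality,
    target_modality,
    source_features: list[str] | None = None,
    target_features: list[str] | None = None,
    groups: np.ndarray | None = None,
    background: np.ndarray | None = None,
) -> RelevanceTable:
    """Within one group, mean |Shapley value| of each source-modality
    feature with respect to each cross-modal predicted target feature,
    computed through the source encoder → target decoder chain."""
    v1 = model.modality_names.index(source_modality) if isinstance(
        source_modality, str
    ) else source_modality
    v2 = model.modality_names.index(target_modality) if isinstance(
        target_modality, str
    ) else target_modality
    if v1 == v2:
        raise ValueError("source and target must be different modalities")
    if groups is None:
        groups, _ = infer_groups(model, dataset)
    members = np.flatnonzero(groups == group)
    if members.size == 0:
        raise ValueError(f"no cells assigned to group {group}")
    src = dataset.modalities[v1]
    tgt = dataset.modalities[v2]
    src_names = source_features or src.feature_names
    tgt_names = target_features or tgt.feature_names
    src_idx = [src.feature_names.index(f) for f in src_names]
    tgt_idx = [tgt.feature_names.index(f) for f in tgt_names]
    calc = src.values[members]
    if background is None:
        background = np.stack(
            [src.values[groups == g].mean(axis=0) for g in np.unique(groups)]
        )
    chain = [model.encoders[v1], model.decoders[v2]]
    rows = []
    scores = np.zeros((len(src_idx), len(tgt_idx)))
    for t_pos, t in enumerate(tgt_idx):
        res = deep_shap(
            chain, calc, background, unit=t,
            target=f"{src.name}->{tgt.name}:{tgt.feature_names[t]}",
        )
        scores[:, t_pos] = np.abs(res.phi).mean(axis=0)[src_idx]
    lo, hi = scores.min(), scores.max()
    normed = (scores - lo) / (hi - lo) if hi > lo else np.zeros_like(scores)
    flat_order = np.argsort(-scores, axis=None, kind="stable")
    rank_flat = np.empty(scores.size, dtype=int)
    rank_flat[flat_order] = np.arange(1, scores.size + 1)
    rank = rank_flat.reshape(scores.shape)
    for i, s_name in enumerate(src_names):
        for j, t_name in enumerate(tgt_names):
            rows.append(
                {
                    "group": group,
                    "modality": f"{src.name}->{tgt.name}",
                    "feature": f"{s_name}->{t_name}",
                    "source": s_name,
                    "target": t_name,
                    "score": scores[i, j],
                    "normalized": normed[i, j],
                    "rank": int(rank[i, j]),
                }
            )
    return RelevanceTable(table=pd.DataFrame(rows))


def relevance_robustness(
    model: UnitedNetModel | None,
    dataset: MultiModalDataset,
    k: int = 10,
    n_top: int = 7,
    mode: str = "fixed_model",
    config: ModelConfig | None = None,
    seed: int = 0,
    max_background_rows: int | None = None,
) -> pd.DataFrame:
    """Cross-validated stability of the top-``n_top`` features.

    Each fold in turn is the calculation data; the remaining k−1 folds
    are the background references.  Returns, per (group, modality,
    feature), the number of replications (out of k) in which the feature
    appears in the top list.  ``retrain_per_fold`` retrains the model on
    the k−1 background folds each time.  ``max_background_rows``
    subsamples the background for tractability on large data (the
    per-group-mean background of :func:`group_feature_relevance` is the
    other large-data option).
    """
    if k < 2:
        raise ValueError("k must be ≥ 2")
    if mode not in ("fixed_model", "retrain_per_fold"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "fixed_model" and model is None:
        raise ValueError("fixed_model mode needs a trained model")
    if mode == "retrain_per_fold" and config is None:
        raise ValueError("retrain_per_fold mode needs a config")
    folds = split_folds(dataset, k, mode="random", seed=seed)
    counts: dict[tuple, int] = {}
    for fold in range(1, k + 1):
        calc_idx = folds.fold_indices(fold)
        bg_idx = np.setdiff1d(np.arange(dataset.n_cells), calc_idx)
        bg_ds = dataset.subset(bg_idx)
        calc_ds = dataset.subset(calc_idx)
        if mode == "retrain_per_fold":
            fold_model = train(bg_ds, config)
        else:
            fold_model = model
        groups, _ = infer_groups(fold_model, calc_ds)
        background = _concat_features(bg_ds)
        if max_background_rows and background.shape[0] > max_background_rows:
            sub_rng = np.random.default_rng(seed + fold)
            keep = sub_rng.choice(
                background.shape[0], size=max_background_rows, replace=False
            )
            background = background[keep]
        rel = group_feature_relevance(
            fold_model, calc_ds, n_top=n_top, groups=groups, background=background
        )
        for g in rel.table["group"].unique():
            for mod in rel.table["modality"].unique():
                for feat in rel.top_features(g, mod):
                    counts[(g, mod, feat)] = counts.get((g, mod, feat), 0) + 1
    rows = [
        {"group": g, "modality": mod, "feature": feat, "frequency": c, "k": k}
        for (g, mod, feat), c in sorted(counts.items(), key=lambda kv: -kv[1])
    ]
    return pd.DataFrame(rows)


def marker_predictability_check(
    relevance: RelevanceTable,
    known_markers: dict[int, dict[str, list[str]]],
    rng: np.random.Generator | None = None,
    n_draws: int = 200,
) -> dict:
    """How well relevance scores separate known markers from random
    features: the probability that a marker outranks a random non-marker
    of the same group/modality (0.5 = chance)."""
    rng = rng or np.random.default_rng(0)
    if not known_markers or all(
        not per_mod for per_mod in known_markers.values()
    ):
        raise ValueError("empty marker lists")
    wins = 0
    total = 0
    per_group = {}
    for group, per_mod in known_markers.items():
        for mod, markers in per_mod.items():
            sub = relevance.table[
                (relevance.table["group"] == group)
                & (relevance.table["modality"] == mod)
            ]
            if sub.empty:
                continue
            score_of = dict(zip(sub["feature"], sub["score"]))
            non_markers = [f for f in sub["feature"] if f not in markers]
            g_wins = g_total = 0
            for marker in markers:
                if marker not in score_of:
                    continue
                if not non_markers:
                    g_wins += n_draws
                    g_total += n_draws
                    continue
                rivals = rng.choice(non_markers, size=n_draws)
                for rival in rivals:
                    g_total += 1
                    if score_of[marker] > score_of[rival]:
                        g_wins += 1
            per_group[(group, mod)] = g_wins / g_total if g_total else np.nan
            wins += g_wins
            total += g_total
    return {
        "accuracy": wins / total if total else np.nan,
        "baseline": 0.5,
        "per_group": per_group,
    }
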