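"""Alternating two-step training, inference entry points, annotation
transfer, and ablation runs.

Each minibatch sees (a) a group-identification step — encoders, fusion
weights, and head updated under the clustering loss (unsupervised) or
the weighted cross-entropy (supervised), repeated ``c × V`` times — and
(b) a prediction step — discriminators updated under the least-squares
discriminator loss, then encoders and decoders updated under the sum of
within-/cross-modality prediction, generator, and contrastive losses.
The three parameter groups have independent Adam optimizers and never
overlap.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .autodiff import Tensor
from .data import MultiModalDataset
from .losses import (
    LossReport,
    adaptive_sigma,
    adversarial_losses,
    classification_loss,
    clustering_loss,
    compose_group_loss,
    compose_pgc_loss,
    contrastive_loss,
    prediction_losses,
)
from .metrics import prediction_metrics
from .network import ModelConfig, UnitedNetModel, assign_groups
from .nn import Adam

logger = logging.getLogger(__name__)

ABLATION_VARIANTS = ("full", "no_prediction_task", "no_group_task", "no_discriminator")

__all__ = [
    "TrainState",
    "PredictionResult",
    "train",
    "infer_groups",
    "predict_cross_modal",
    "transfer_annotations",
    "run_ablation",
    "ABLATION_VARIANTS",
]


@dataclass
class TrainState:
    mode: str
    epoch: int = 0
    history: list[dict] = field(default_factory=list)
    eta_history: list[np.ndarray] = field(default_factory=list)

    def write_log(self, path) -> None:
        if not self.history:
            return
        keys = sorted({k for row in self.history for k in row})
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(self.history)


@dataclass
class PredictionResult:
    source: str
    target: str
    predicted: np.ndarray
    metrics: dict


def _check_finite(value: float, name: str, epoch: int, step: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(
            f"{name} became non-finite at epoch {epoch}, step {step}; aborting"
        )


def train(
    dataset: MultiModalDataset,
    config: ModelConfig,
    variant: str = "full",
    return_state: bool = False,
    checkpoint_callback=None,
):
    """Train a model on ``dataset``; returns the trained model.

    ``variant`` selects an ablation: ``no_prediction_task`` skips the
    whole prediction step, ``no_group_task`` skips the group step, and
    ``no_discriminator`` drops the adversarial and contrastive terms
    (two coupled autoencoders without latent alignment).
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {ABLATION_VARIANTS}")
    if config.mode == "supervised":
        if dataset.labels is None:
            raise ValueError("supervised mode requires labels")
        if dataset.labels.max() > config.n_groups:
            raise ValueError("labels exceed the configured number of groups")
    if config.n_groups > dataset.n_cells:
        raise ValueError("more groups than cells")

    model = UnitedNetModel(
        config,
        [m.n_features for m in dataset.modalities],
        [m.is_binary for m in dataset.modalities],
        [m.name for m in dataset.modalities],
    )
    V = model.n_modalities
    rng = np.random.default_rng(config.seed)
    opt_group = Adam(
        model.group_identification_parameters(),
        lr=config.learning_rate,
        clip_norm=config.grad_clip,
    )
    opt_gen = Adam(
        model.generator_parameters(),
        lr=config.learning_rate,
        clip_norm=config.grad_clip,
    )
    opt_dis = Adam(
        model.discriminator_parameters(),
        lr=config.learning_rate,
        clip_norm=config.grad_clip,
    )
    state = TrainState(mode=config.mode)
    n = dataset.n_cells
    X_all = [m.values for m in dataset.modalities]
    binary_flags = model.binary_flags
    class_counts = None
    if dataset.labels is not None:
        class_counts = np.bincount(dataset.labels, minlength=config.n_groups + 1)[1:]

    # `no_discriminator` is the dual-autoencoder baseline: two vanilla
    # autoencoders — within-modality reconstruction only, no adversarial
    # game, no contrastive alignment, no group-identification coupling.
    do_group = variant not in ("no_group_task", "no_discriminator")
    do_pred = variant != "no_prediction_task"
    do_cross = variant != "no_discriminator"
    do_adversarial = variant not in ("no_discriminator",)
    do_contrastive = variant not in ("no_discriminator",)

    for epoch in range(config.epochs):
        state.epoch = epoch
        perm = rng.permutation(n)
        for step, start in enumerate(range(0, n, config.batch_size)):
            idx = perm[start : start + config.batch_size]
            if idx.size < 2:
                continue  # loss terms are batch statistics; skip singletons
            Xb = [X[idx] for X in X_all]
            report = LossReport()

            if do_group:
                for _ in range(config.clustering_repeat * V):
                    codes = [model.encode(v, Xb[v], train=True) for v in range(V)]
                    fused = model.fuse(codes)
                    h, alpha = model.head_forward(fused, train=True)
                    if config.mode == "unsupervised":
                        sigma = adaptive_sigma(h.data, config.sigma_rel)
                        parts = clustering_loss(h, alpha, sigma)
                        l_group = compose_group_loss(parts, "unsupervised")
                        report.record(
                            L_c1=parts[0], L_c2=parts[1], L_c3=parts[2]
                        )
                    else:
                        l_entropy = classification_loss(
                            alpha,
                            dataset.labels[idx],
                            class_counts,
                            inverse_frequency=config.inverse_frequency_weights,
                        )
                        l_group = compose_group_loss((l_entropy,), "supervised")
                        report.record(L_entropy=l_entropy)
                    _check_finite(l_group.item(), "L_group", epoch, step)
                    report.record(L_group=l_group)
                    opt_group.zero_grad()
                    l_group.backward()
                    opt_group.step()

            if do_pred:
                codes = [model.encode(v, Xb[v], train=True) for v in range(V)]
                within = [model.decode(v, codes[v], train=True) for v in range(V)]
                cross = (
                    {
                        (v1, v2): model.decode(v2, codes[v1], train=True)
                        for v1, v2 in combinations(range(V), 2)
                    }
                    if do_cross
                    else {}
                )

                if do_adversarial:
                    real = [
                        model.discriminate(v, Xb[v], train=True) for v in range(V)
                    ]
                    fake_detached = [
                        model.discriminate(v, within[v].data, train=True)
                        for v in range(V)
                    ]
                    _, l_dis = adversarial_losses(real, fake_detached)
                    _check_finite(l_dis.item(), "L_Dis", epoch, step)
                    report.record(L_Dis=l_dis)
                    opt_dis.zero_grad()
                    l_dis.backward()
                    opt_dis.step()

                if do_adversarial:
                    fake = [
                        model.discriminate(v, within[v], train=True)
                        for v in range(V)
                    ]
                    l_gen, _ = adversarial_losses(fake, fake)  # only fake term used
                else:
                    l_gen = Tensor(0.0)

                l_w, l_c = prediction_losses(Xb, within, cross, binary_flags)

                if do_contrastive and config.delta > 0:
                    if config.mode == "supervised":
                        groups = dataset.labels[idx]
                    else:
                        with np.errstate(all="ignore"):
                            _, alpha_inf = model.head_forward(
                                model.fuse(
                                    [Tensor(c.data) for c in codes]
                                )
                            )
                        groups = assign_groups(alpha_inf.data)
                    l_con = contrastive_loss(
                        codes,
                        groups,
                        config.tau,
                        config.delta,
                        config.neg_sample_size,
                        rng,
                        include_positive=config.include_positive_in_denominator,
                    )
                else:
                    l_con = Tensor(0.0)

                l_pgc = compose_pgc_loss((l_w, l_c, l_gen, l_con))
                _check_finite(l_pgc.item(), "L_PGC", epoch, step)
                report.record(
                    L_Wpredict=l_w, L_Cpredict=l_c, L_Gen=l_gen, L_Con=l_con,
                    L_PGC=l_pgc,
                )
                opt_gen.zero_grad()
                l_pgc.backward()
                opt_gen.step()

            row = {"epoch": epoch, "step": step}
            row.update(report.as_dict())
            state.history.append(row)
        state.eta_history.append(model.eta.copy())
        if checkpoint_callback is not None:
            checkpoint_callback(epoch, model)

    model.train_state = state
    if return_state:
        return model, state
    return model


def infer_groups(
    model: UnitedNetModel, dataset: MultiModalDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic inference: labels (1..K) and soft assignments α."""
    bundle = model.forward_bundle(dataset, train=False)
    return assign_groups(bundle.alpha), bundle.alpha


def predict_cross_modal(
    model: UnitedNetModel, dataset: MultiModalDataset, v1, v2
) -> PredictionResult:
    """Predict modality ``v2`` from modality ``v1``; R² for continuous
    targets, AUC for binary targets."""
    i1 = model.modality_names.index(v1) if isinstance(v1, str) else v1
    i2 = model.modality_names.index(v2) if isinstance(v2, str) else v2
    if not (0 <= i1 < model.n_modalities and 0 <= i2 < model.n_modalities):
        raise ValueError("unknown modality")
    if i1 == i2:
        raise ValueError("source and target modality must differ")
    codes = model.encode(i1, dataset.modalities[i1].values)
    pred = model.decode(i2, codes).data
    target = dataset.modalities[i2].values
    metrics = prediction_metrics(target, pred, binary=model.binary_flags[i2])
    return PredictionResult(
        source=model.modality_names[i1],
        target=model.modality_names[i2],
        predicted=pred,
        metrics=metrics,
    )


def transfer_annotations(
    config: ModelConfig,
    reference: MultiModalDataset,
    query: MultiModalDataset,
    return_model: bool = False,
):
    """Train supervised on the labeled reference, then classify the query
    through the shared latent space."""
    if reference.labels is None:
        raise ValueError("reference dataset must carry labels")
    mismatches = []
    for mr, mq in zip(reference.modalities, query.modalities):
        if mr.feature_names != mq.feature_names:
            diff = sorted(set(mr.feature_names) ^ set(mq.feature_names))[:5]
            mismatches.append(f"{mr.name}: {diff}")
    if mismatches:
        raise ValueError(
            "reference/query feature spaces differ — " + "; ".join(mismatches)
        )
    cfg = ModelConfig(**{**config.__dict__, "mode": "supervised"})
    model = train(reference, cfg)
    labels, alpha = infer_groups(model, query)
    if return_model:
        return labels, alpha, model
    return labels, alpha


def run_ablation(
    dataset: MultiModalDataset,
    config: ModelConfig,
    variants: tuple[str, ...] = ABLATION_VARIANTS,
) -> dict[str, dict]:
    """Train each named variant under identical seed/epochs and report
    ARI (against labels, when present) plus per-direction prediction
    metrics."""
    from .metrics import ari as _ari

    results: dict[str, dict] = {}
    for variant in variants:
        model = train(dataset, config, variant=variant)
        entry: dict = {"variant": variant}
        labels, _ = infer_groups(model, dataset)
        if dataset.labels is not None:
            entry["ari"] = _ari(labels, dataset.labels)
        preds = {}
        for v1, v2 in combinations(range(model.n_modalities), 2):
            for a, b in ((v1, v2), (v2, v1)):
                res = predict_cross_modal(model, dataset, a, b)
                preds[f"{res.source}->{res.target}"] = res.metrics["overall"]
        entry["prediction_overall"] = preds
        entry["prediction_mean"] = float(np.nanmean(list(preds.values())))
        results[variant] = entry
    return results
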