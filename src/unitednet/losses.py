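"""Training objectives: divergence-based clustering, prediction,
least-squares adversarial, contrastive alignment, and weighted
classification losses, plus the two composite objectives used by the
alternating training procedure.

Every loss accepts and returns autodiff tensors, so analytic gradients
are available for any parameter upstream of its inputs.  Batch-dependent
quantities (the similarity kernel, the mean soft assignment, the
negative-sampling pool) are computed per minibatch.

Numerical guards: ``EPS = 1e-9`` protects divisions and logarithms; the
per-cell prediction norms carry a tiny additive constant inside the
square root so the gradient stays finite at perfect reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist

from .autodiff import Tensor, concatenate

logger = logging.getLogger(__name__)

EPS = 1e-9
_NORM_EPS = 1e-12

__all__ = [
    "EPS",
    "LossReport",
    "similarity_kernel",
    "adaptive_sigma",
    "clustering_loss",
    "prediction_losses",
    "adversarial_losses",
    "contrastive_loss",
    "classification_loss",
    "compose_group_loss",
    "compose_pgc_loss",
]


@dataclass
class LossReport:
    """Named scalar loss values for one training step."""

    values: dict = field(default_factory=dict)

    def record(self, **kwargs):
        for k, v in kwargs.items():
            self.values[k] = float(v.item() if isinstance(v, Tensor) else v)

    def as_dict(self) -> dict:
        return dict(self.values)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


# ------------------------------------------------------------- clustering


def adaptive_sigma(h: np.ndarray, sigma_rel: float) -> float:
    """Kernel bandwidth σ = sigma_rel × median pairwise distance of h."""
    if h.shape[0] < 2:
        return max(sigma_rel, EPS)
    med = float(np.median(pdist(h)))
    return max(sigma_rel * med, EPS)


def similarity_kernel(h: Tensor, sigma: float) -> Tensor:
    """Gaussian similarity s_ij = exp(−‖h_i − h_j‖² / (2σ²))."""
    h = _as_tensor(h)
    sq = (h * h).sum(axis=1, keepdims=True)
    d2 = (sq + sq.T - 2.0 * (h @ h.T)).clip_min(0.0)
    return (d2 * (-1.0 / (2.0 * sigma**2))).exp()


def _cauchy_schwarz_divergence(A: Tensor, S: Tensor, K: int) -> Tensor:
    """Mean over pairs k<l of  a_kᵀ S a_l / √(a_kᵀ S a_k · a_lᵀ S a_l)."""
    M = A.T @ S @ A  # (K, K)
    idx = np.arange(K)
    d = M[(idx, idx)]  # diagonal, shape (K,)
    denom = ((d.reshape(K, 1) @ d.reshape(1, K)) + EPS).sqrt()
    ratio = M / denom
    upper = np.triu(np.ones((K, K)), k=1)
    n_pairs = K * (K - 1) / 2
    return (ratio * upper).sum() * (1.0 / n_pairs)


def clustering_loss(
    h: Tensor, alpha: Tensor, sigma: float
) -> tuple[Tensor, Tensor, Tensor]:
    """The three-component divergence clustering loss.

    Component 1 decorrelates the soft assignments of different groups
    under the similarity kernel; component 2 does the same for the
    simplex-corner proximities exp(−‖α_i − e_k‖²); component 3 is the
    negative entropy of the mean assignment, minimized at the uniform
    distribution where it equals −log K.
    """
    h, alpha = _as_tensor(h), _as_tensor(alpha)
    n, K = alpha.shape
    if n < 2 or K < 2:
        raise ValueError("clustering loss needs n ≥ 2 cells and K ≥ 2 groups")
    S = similarity_kernel(h, sigma)
    l_c1 = _cauchy_schwarz_divergence(alpha, S, K)
    # ‖α_i − e_k‖² = ‖α_i‖² − 2 α_ik + 1
    sq = (alpha * alpha).sum(axis=1, keepdims=True)
    m = ((sq - 2.0 * alpha + 1.0) * -1.0).exp()  # (n, K), entries in (0, 1]
    l_c2 = _cauchy_schwarz_divergence(m, S, K)
    abar = alpha.mean(axis=0)
    l_c3 = (abar * abar.clip_min(EPS).log()).sum()
    return l_c1, l_c2, l_c3


# ------------------------------------------------------------- prediction


def _bce(pred: Tensor, target: np.ndarray) -> Tensor:
    if (pred.data < 0).any() or (pred.data > 1).any():
        raise ValueError("binary modality predictions must lie in [0, 1]")
    p = pred.clip_min(EPS)
    q = (1.0 - pred).clip_min(EPS)
    t = np.asarray(target, dtype=np.float64)
    return -(t * p.log() + (1.0 - t) * q.log()).mean()


def _mean_row_norm(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - np.asarray(target, dtype=np.float64)
    return diff.row_norm(eps=_NORM_EPS).mean()


def prediction_losses(
    targets: list[np.ndarray],
    within_preds: list[Tensor],
    cross_preds: dict[tuple[int, int], Tensor],
    binary_flags: list[bool],
) -> tuple[Tensor, Tensor]:
    """Within- and cross-modality prediction losses.

    Continuous modalities contribute the per-cell Euclidean norm of the
    residual, averaged over cells and modalities (within) or unordered
    modality pairs taken as v1 < v2 (cross).  Binary modalities
    contribute the mean binary cross-entropy instead.

    ``cross_preds`` maps (source, target) modality index pairs to the
    predicted target features.
    """
    V = len(targets)
    if len(within_preds) != V:
        raise ValueError("one within-modality prediction per modality required")
    terms = []
    for v in range(V):
        if within_preds[v].shape != targets[v].shape:
            raise ValueError(f"within prediction {v}: shape mismatch")
        if binary_flags[v]:
            terms.append(_bce(within_preds[v], targets[v]))
        else:
            terms.append(_mean_row_norm(within_preds[v], targets[v]))
    l_w = terms[0]
    for t in terms[1:]:
        l_w = l_w + t
    l_w = l_w * (1.0 / V)

    cross_terms = []
    for (v1, v2), pred in cross_preds.items():
        if pred.shape != targets[v2].shape:
            raise ValueError(f"cross prediction {v1}->{v2}: shape mismatch")
        if binary_flags[v2]:
            cross_terms.append(_bce(pred, targets[v2]))
        else:
            cross_terms.append(_mean_row_norm(pred, targets[v2]))
    if not cross_terms:
        return l_w, Tensor(0.0)
    l_c = cross_terms[0]
    for t in cross_terms[1:]:
        l_c = l_c + t
    l_c = l_c * (1.0 / len(cross_terms))
    return l_w, l_c


# ------------------------------------------------------------ adversarial


def adversarial_losses(
    real_scores: list[Tensor], fake_scores: list[Tensor]
) -> tuple[Tensor, Tensor]:
    """Least-squares adversarial objectives.

    Generator: mean (Dis(x̃) − 1)², minimized when every reconstruction
    fools the discriminator.  Discriminator: mean Dis(x̃)² +
    mean (Dis(x) − 1)², minimized when reconstructions score 0 and real
    data scores 1.
    """
    gen_terms, dis_terms = [], []
    for real, fake in zip(real_scores, fake_scores):
        gen_terms.append(((fake - 1.0) ** 2).mean())
        dis_terms.append((fake**2).mean() + ((real - 1.0) ** 2).mean())
    V = len(gen_terms)
    l_gen = gen_terms[0]
    l_dis = dis_terms[0]
    for t in gen_terms[1:]:
        l_gen = l_gen + t
    for t in dis_terms[1:]:
        l_dis = l_dis + t
    return l_gen * (1.0 / V), l_dis * (1.0 / V)


# ------------------------------------------------------------- contrastive


def contrastive_loss(
    codes: list[Tensor],
    group_assign: np.ndarray,
    tau: float,
    delta: float,
    neg_size: int,
    rng: np.random.Generator,
    include_positive: bool = False,
) -> Tensor:
    """Contrastive alignment of per-cell codes across modalities.

    For each unordered modality pair the positive is the cell's own
    cross-modal cosine similarity; negatives are sampled from the cosine
    similarities (over all ordered modality pairs, including
    within-modality) between the cell and cells whose assigned group
    differs.  As printed, the positive term is absent from the
    denominator, so individual terms can be negative; the standard
    InfoNCE form is available via ``include_positive``.

    Cells with no eligible negative (everyone shares their group) are
    skipped with a warning.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    V = len(codes)
    if V < 2:
        raise ValueError("need at least two modalities")
    codes = [_as_tensor(z) for z in codes]
    n = codes[0].shape[0]
    group_assign = np.asarray(group_assign)
    normed = [z / z.row_norm(eps=_NORM_EPS) for z in codes]

    pairs = [(a, b) for a in range(V) for b in range(V)]
    sims = {p: normed[p[0]] @ normed[p[1]].T for p in pairs}  # each (n, n)
    big = concatenate([sims[p] for p in pairs], axis=1)  # (n, V²·n)

    diff_group = group_assign[None, :] != group_assign[:, None]  # (n, n)
    not_self = ~np.eye(n, dtype=bool)
    valid = diff_group & not_self  # same for every modality pair
    eligible = valid.any(axis=1)
    if not eligible.any():
        logger.warning("contrastive loss: no cell has an eligible negative; skipped")
        return Tensor(0.0)
    if not eligible.all():
        logger.warning(
            "contrastive loss: %d cells with no eligible negative skipped",
            int((~eligible).sum()),
        )

    rows_idx = np.flatnonzero(eligible)
    n_eff = rows_idx.size
    # sample negative columns of `big` per eligible cell
    neg_cols = np.empty((n_eff, 0), dtype=int)
    col_lists = []
    for i in rows_idx:
        cand_j = np.flatnonzero(valid[i])
        # candidate pool spans all ordered modality pairs
        cand = (np.arange(len(pairs))[:, None] * n + cand_j[None, :]).ravel()
        take = min(neg_size, cand.size)
        col_lists.append(rng.choice(cand, size=take, replace=False))
    width = min(len(c) for c in col_lists)
    neg_cols = np.stack([c[:width] for c in col_lists])

    gathered = big[(np.repeat(rows_idx, width), neg_cols.ravel())].reshape(
        n_eff, width
    )
    denom_exp = (gathered * (1.0 / tau)).exp().sum(axis=1)  # (n_eff,)

    total = Tensor(0.0)
    n_pairs = V * (V - 1) / 2
    idx = (rows_idx, rows_idx)
    for v1, v2 in combinations(range(V), 2):
        pos = sims[(v1, v2)][idx]  # s_ii for eligible cells
        denom = denom_exp
        if include_positive:
            denom = denom + (pos * (1.0 / tau)).exp()
        l_i = denom.clip_min(EPS).log() - pos * (1.0 / tau)
        total = total + l_i.sum()
    return total * (delta / (n * n_pairs))


# ----------------------------------------------------------- classification


def classification_loss(
    alpha: Tensor,
    labels: np.ndarray,
    class_counts: np.ndarray | None = None,
    inverse_frequency: bool = False,
) -> Tensor:
    """Weighted cross-entropy on the soft assignments.

    The printed weight is g_i = n_k(i)/n, the frequency of the cell's own
    class; ``inverse_frequency`` swaps in 1/(K · n_k(i)/n).
    """
    alpha = _as_tensor(alpha)
    n, K = alpha.shape
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 1 or labels.max() > K:
        raise ValueError(f"labels must lie in 1..{K}")
    if class_counts is None:
        class_counts = np.bincount(labels, minlength=K + 1)[1:]
    total = float(np.asarray(class_counts).sum())
    freq = np.asarray(class_counts, dtype=np.float64) / total
    g = freq[labels - 1]
    if inverse_frequency:
        g = 1.0 / (K * np.maximum(g, EPS))
    picked = alpha[(np.arange(n), labels - 1)].clip_min(EPS)
    return -(picked.log() * g).sum() * (1.0 / n)


# -------------------------------------------------------------- composites


def compose_group_loss(parts, mode: str) -> Tensor:
    """Unsupervised: L_c1 + L_c2 + L_c3.  Supervised: the classification
    cross-entropy.  Plain sums, no extra weights."""
    if mode == "unsupervised":
        l_c1, l_c2, l_c3 = parts
        return _as_tensor(l_c1) + _as_tensor(l_c2) + _as_tensor(l_c3)
    if mode == "supervised":
        (l_entropy,) = parts if isinstance(parts, (tuple, list)) else (parts,)
        return _as_tensor(l_entropy)
    raise ValueError(f"unknown mode {mode!r}")


def compose_pgc_loss(parts) -> Tensor:
    """L_Wpredict + L_Cpredict + L_Gen + L_Con — unweighted sum."""
    l_w, l_c, l_gen, l_con = parts
    return _as_tensor(l_w) + _as_tensor(l_c) + _as_tensor(l_gen) + _as_tensor(l_con)
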