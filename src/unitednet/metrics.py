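"""Evaluation metrics, implemented from their defining formulas.

ARI via the pair-counting contingency form, R² against the constant-mean
baseline, Pearson's r as the centered cosine, and AUC by exhaustive pair
counting.  The printed AUC indicator is strict (ties contribute 0); the
conventional tie = 0.5 treatment is available as an option.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ari", "r_squared", "pearson", "auc", "prediction_metrics"]


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1) / 2.0


def ari(pred_labels, true_labels) -> float:
    """Adjusted Rand index between two partitions (label values arbitrary)."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("label vectors must be 1-D and the same length")
    n = pred.size
    if n < 2:
        raise ValueError("need at least two cells")
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(true, return_inverse=True)
    table = np.zeros((pi.max() + 1, ti.max() + 1))
    np.add.at(table, (pi, ti), 1)
    sum_cells = _comb2(table).sum()
    sum_a = _comb2(table.sum(axis=1)).sum()
    sum_b = _comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / _comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination: 1 − ‖ỹ−y‖² / ‖ȳ−y‖²."""
    y = np.asarray(y_true, dtype=np.float64).ravel()
    yt = np.asarray(y_pred, dtype=np.float64).ravel()
    if y.shape != yt.shape:
        raise ValueError("length mismatch")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("y_true is constant; R² undefined")
    ss_res = float(((yt - y) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def pearson(y_true, y_pred) -> float:
    """Pearson correlation as the cosine of the centered vectors."""
    y = np.asarray(y_true, dtype=np.float64).ravel()
    yt = np.asarray(y_pred, dtype=np.float64).ravel()
    if y.shape != yt.shape:
        raise ValueError("length mismatch")
    yc = y - y.mean()
    ytc = yt - yt.mean()
    ny, nyt = np.linalg.norm(yc), np.linalg.norm(ytc)
    if ny == 0 or nyt == 0:
        raise ValueError("constant vector; correlation undefined")
    return float(yc @ ytc / (ny * nyt))


def auc(y_true_binary, scores, ties: str = "strict") -> float:
    """Pairwise-counting AUC.

    ``ties='strict'`` counts a tied (negative, positive) score pair as 0,
    per the strict indicator; ``ties='half'`` counts it as 0.5 (the
    conventional ROC value).
    """
    y = np.asarray(y_true_binary).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.shape != s.shape:
        raise ValueError("length mismatch")
    p0 = s[y == 0]
    p1 = s[y == 1]
    if p0.size == 0 or p1.size == 0:
        raise ValueError("both classes must be present")
    wins = (p0[:, None] < p1[None, :]).sum()
    if ties == "half":
        wins = wins + 0.5 * (p0[:, None] == p1[None, :]).sum()
    elif ties != "strict":
        raise ValueError("ties must be 'strict' or 'half'")
    return float(wins / (p0.size * p1.size))


def prediction_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, binary: bool = False
) -> dict:
    """Overall (flattened) and per-feature R² or AUC for a prediction matrix.

    Per-feature values are NaN where undefined (constant truth column or
    single-class binary column).
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    metric = auc if binary else r_squared
    per_feature = np.full(y_true.shape[1], np.nan)
    for j in range(y_true.shape[1]):
        try:
            per_feature[j] = metric(y_true[:, j], y_pred[:, j])
        except ValueError:
            pass
    try:
        overall = metric(y_true.ravel(), y_pred.ravel())
    except ValueError:
        overall = np.nan
    return {
        "metric": "auc" if binary else "r2",
        "overall": overall,
        "per_feature": per_feature,
        "per_feature_mean": float(np.nanmean(per_feature))
        if np.isfinite(per_feature).any()
        else np.nan,
    }
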