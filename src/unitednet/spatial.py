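"""Spatial context: the niche modality and label refinement.

The niche modality replaces each cell's feature vector with an
inverse-distance-weighted average over its J nearest spatial neighbors
(self excluded), turning neighborhood expression into an extra modality.
Label refinement reassigns each spot to the strict majority label of its
spatial neighborhood, in a single pass.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.spatial import cKDTree

from .data import ModalityMatrix

__all__ = ["build_niche_modality", "refine_labels"]


def _neighbor_table(coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices/distances of the k nearest neighbors, self excluded,
    ties broken deterministically by cell index."""
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be n × 2")
    if k >= n:
        raise ValueError(f"neighbor count {k} must be < number of cells {n}")
    tree = cKDTree(coords)
    dist, idx = tree.query(coords, k=n)  # full ordering for deterministic ties
    dist, idx = np.atleast_2d(dist), np.atleast_2d(idx)
    out_idx = np.empty((n, k), dtype=int)
    out_dist = np.empty((n, k))
    for i in range(n):
        order = np.lexsort((idx[i], dist[i]))  # distance, then index
        row_i, row_d = idx[i][order], dist[i][order]
        keep = row_i != i
        out_idx[i] = row_i[keep][:k]
        out_dist[i] = row_d[keep][:k]
    return out_idx, out_dist


def build_niche_modality(
    m: ModalityMatrix, coords: np.ndarray, J: int = 10
) -> ModalityMatrix:
    """Inverse-distance-weighted neighborhood average of ``m``.

    Weights are 1/distance normalized to sum to one per cell.  A neighbor
    at zero distance takes the full weight (the limit of the rule); if
    several neighbors are at zero distance, the weight is shared equally
    among them.
    """
    nbr_idx, nbr_dist = _neighbor_table(coords, J)
    n = m.n_cells
    weights = np.empty_like(nbr_dist)
    for i in range(n):
        d = nbr_dist[i]
        zero = d == 0
        if zero.any():
            weights[i] = zero / zero.sum()
        else:
            inv = 1.0 / d
            weights[i] = inv / inv.sum()
    niche = np.einsum("ij,ijf->if", weights, m.values[nbr_idx])
    return replace(
        m,
        name=f"{m.name}_niche",
        values=niche,
        feature_names=[f"{f}_niche" for f in m.feature_names],
        is_binary=False,
    )


def refine_labels(
    labels: np.ndarray, coords: np.ndarray, n_neighbors: int = 35
) -> np.ndarray:
    """Single-pass spatial smoothing of group labels.

    Each cell is reassigned to the majority label among its
    ``n_neighbors`` nearest spots when that majority is strict (> 50% of
    the neighborhood); otherwise its label is kept.  All reassignments
    use the original labels (synchronous update).
    """
    labels = np.asarray(labels)
    nbr_idx, _ = _neighbor_table(coords, n_neighbors)
    out = labels.copy()
    for i in range(labels.size):
        nbr_labels = labels[nbr_idx[i]]
        values, counts = np.unique(nbr_labels, return_counts=True)
        top = counts.argmax()
        if counts[top] > n_neighbors / 2:
            out[i] = values[top]
    return out
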