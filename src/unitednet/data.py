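"""Multi-modality dataset containers, readers/writers, and preprocessing.

A dataset is a list of per-modality feature matrices over the same cells,
in the same cell order, with optional group labels (1..K), batch
identifiers, and 2-D spatial coordinates.  Supported on-disk formats:

* dense CSV/TSV — cells × features, header row = feature names, first
  column = cell identifier;
* MatrixMarket ``.mtx`` (cells × features) with ``<stem>_barcodes.tsv``
  and ``<stem>_features.tsv`` sidecars;
* ``.h5ad`` — one AnnData per modality, matrix in ``X``.

Preprocessing follows the conventions standard for each data type:
per-cell standardization for continuous multi-sensing features,
median-total normalization + log1p for counts, binarization for
accessibility-like data, and top-variance feature selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ModalityMatrix",
    "MultiModalDataset",
    "FoldSplit",
    "load_modality",
    "save_modality",
    "load_dataset",
    "standardize_cells",
    "standardize_features",
    "normalize_log1p",
    "binarize",
    "select_top_variable",
    "split_folds",
]


@dataclass
class ModalityMatrix:
    """One modality's cells × features matrix with feature names."""

    name: str
    values: np.ndarray
    feature_names: list[str]
    is_binary: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"modality {self.name!r}: values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"modality {self.name!r}: non-finite entries")
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError(
                f"modality {self.name!r}: {len(self.feature_names)} feature names "
                f"for {self.values.shape[1]} columns"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError(f"modality {self.name!r}: duplicate feature names")
        if self.is_binary and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError(f"modality {self.name!r}: flagged binary but not 0/1")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class MultiModalDataset:
    """Aligned per-cell matrices across V ≥ 2 modalities (V = 1 allowed
    transiently for construction; training requires ≥ 2)."""

    modalities: list[ModalityMatrix]
    labels: np.ndarray | None = None  # per-cell group index in {1..K}
    batch_ids: np.ndarray | None = None
    coords: np.ndarray | None = None  # n × 2 spatial coordinates
    cell_ids: list[str] | None = None
    marker_truth: dict = field(default_factory=dict)  # group -> {modality: [features]}

    def __post_init__(self):
        if not self.modalities:
            raise ValueError("dataset needs at least one modality")
        n = self.modalities[0].n_cells
        for m in self.modalities:
            if m.n_cells != n:
                raise ValueError(
                    f"modality {m.name!r} has {m.n_cells} cells, expected {n}"
                )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels must be one integer per cell")
            if self.labels.min() < 1:
                raise ValueError("labels must lie in {1..K}")
        if self.batch_ids is not None:
            self.batch_ids = np.asarray(self.batch_ids)
            if self.batch_ids.shape[0] != n:
                raise ValueError("batch_ids must be one per cell")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.float64)
            if self.coords.shape != (n, 2):
                raise ValueError("coords must be n × 2")
        if self.cell_ids is not None and len(self.cell_ids) != n:
            raise ValueError("cell_ids must be one per cell")

    @property
    def n_cells(self) -> int:
        return self.modalities[0].n_cells

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    @property
    def n_groups(self) -> int:
        if self.labels is None:
            raise ValueError("dataset has no labels")
        return int(self.labels.max())

    def modality(self, name_or_index) -> ModalityMatrix:
        if isinstance(name_or_index, int):
            return self.modalities[name_or_index]
        for m in self.modalities:
            if m.name == name_or_index:
                return m
        raise KeyError(f"no modality named {name_or_index!r}")

    def modality_index(self, name_or_index) -> int:
        if isinstance(name_or_index, int):
            if not 0 <= name_or_index < len(self.modalities):
                raise KeyError(f"modality index {name_or_index} out of range")
            return name_or_index
        for i, m in enumerate(self.modalities):
            if m.name == name_or_index:
                return i
        raise KeyError(f"no modality named {name_or_index!r}")

    def subset(self, idx: np.ndarray) -> "MultiModalDataset":
        """Row-subset every aligned array by integer or boolean index."""
        idx = np.asarray(idx)
        return MultiModalDataset(
            modalities=[replace(m, values=m.values[idx]) for m in self.modalities],
            labels=None if self.labels is None else self.labels[idx],
            batch_ids=None if self.batch_ids is None else self.batch_ids[idx],
            coords=None if self.coords is None else self.coords[idx],
            cell_ids=None
            if self.cell_ids is None
            else [self.cell_ids[i] for i in np.arange(self.n_cells)[idx]],
            marker_truth=self.marker_truth,
        )


@dataclass
class FoldSplit:
    fold_assignment: np.ndarray  # per-cell integer in {1..k}
    seed: int

    @property
    def k(self) -> int:
        return int(self.fold_assignment.max())

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignment == fold)


# --------------------------------------------------------------------- I/O


def _read_csv(path: Path, sep: str) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any() and not df[col].isna().any():
                i = int(np.flatnonzero(coerced.isna())[0])
                raise ValueError(
                    f"{path}: non-numeric entry at row {df.index[i]!r}, "
                    f"column {col!r}"
                ) from exc
        raise
    return values, [str(c) for c in df.index], [str(c) for c in df.columns]


def load_modality(
    path: str | Path, name: str | None = None, fmt: str | None = None
) -> tuple[ModalityMatrix, list[str]]:
    """Read one modality; returns (matrix, cell identifiers)."""
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx", ".h5ad": "h5ad"}.get(
            path.suffix, None
        )
        if fmt is None:
            raise ValueError(f"cannot infer format of {path}")
    name = name or path.stem
    if fmt in ("csv", "tsv"):
        values, cells, feats = _read_csv(path, "," if fmt == "csv" else "\t")
    elif fmt == "mtx":
        from scipy.io import mmread

        values = np.asarray(mmread(path).todense(), dtype=np.float64)
        stem = path.with_suffix("")
        cells = (
            pd.read_csv(f"{stem}_barcodes.tsv", header=None, sep="\t")[0]
            .astype(str)
            .tolist()
        )
        feats = (
            pd.read_csv(f"{stem}_features.tsv", header=None, sep="\t")[0]
            .astype(str)
            .tolist()
        )
        if values.shape != (len(cells), len(feats)):
            raise ValueError(
                f"{path}: matrix shape {values.shape} does not match sidecars "
                f"({len(cells)} barcodes, {len(feats)} features)"
            )
    elif fmt == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X
        values = np.asarray(X.todense() if hasattr(X, "todense") else X, dtype=np.float64)
        cells = adata.obs_names.astype(str).tolist()
        feats = adata.var_names.astype(str).tolist()
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return ModalityMatrix(name=name, values=values, feature_names=feats), cells


def save_modality(
    m: ModalityMatrix, path: str | Path, cell_ids: list[str], fmt: str | None = None
) -> None:
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx", ".h5ad": "h5ad"}[path.suffix]
    if fmt in ("csv", "tsv"):
        pd.DataFrame(m.values, index=cell_ids, columns=m.feature_names).to_csv(
            path, sep="," if fmt == "csv" else "\t"
        )
    elif fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(m.values))
        stem = path.with_suffix("")
        pd.Series(cell_ids).to_csv(f"{stem}_barcodes.tsv", index=False, header=False)
        pd.Series(m.feature_names).to_csv(
            f"{stem}_features.tsv", index=False, header=False
        )
    elif fmt == "h5ad":
        import anndata as ad

        adata = ad.AnnData(X=m.values.copy())
        adata.obs_names = cell_ids
        adata.var_names = m.feature_names
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_dataset(
    modality_paths: dict[str, str | Path],
    labels_path: str | Path | None = None,
    coords_path: str | Path | None = None,
) -> MultiModalDataset:
    """Assemble a dataset from per-modality files.

    Cell order is taken from the first modality; the others are reindexed
    by shared cell identifiers.  A modality whose cell-identifier set does
    not match raises an alignment error naming it.
    """
    modalities: list[ModalityMatrix] = []
    ref_cells: list[str] | None = None
    for name, path in modality_paths.items():
        m, cells = load_modality(path, name=name)
        if ref_cells is None:
            ref_cells = cells
        elif cells != ref_cells:
            if set(cells) != set(ref_cells):
                missing = sorted(set(ref_cells) ^ set(cells))[:5]
                raise ValueError(
                    f"modality {name!r}: cell identifiers do not match the first "
                    f"modality (e.g. {missing})"
                )
            order = [cells.index(c) for c in ref_cells]
            m = replace(m, values=m.values[order])
        modalities.append(m)
    labels = batch_ids = None
    if labels_path is not None:
        df = pd.read_csv(labels_path, index_col=0)
        df = df.loc[ref_cells]
        labels = df.iloc[:, 0].to_numpy(dtype=int)
        if "batch" in df.columns:
            batch_ids = df["batch"].to_numpy()
    coords = None
    if coords_path is not None:
        coords = pd.read_csv(coords_path, index_col=0).loc[ref_cells].to_numpy()
    return MultiModalDataset(
        modalities=modalities,
        labels=labels,
        batch_ids=batch_ids,
        coords=coords,
        cell_ids=ref_cells,
    )


# ----------------------------------------------------------- preprocessing


def standardize_cells(m: ModalityMatrix, ddof: int = 0) -> ModalityMatrix:
    """Per-cell standardization: every row to mean 0, (population) SD 1."""
    if m.is_binary:
        raise ValueError(f"modality {m.name!r}: refusing to standardize binary data")
    sd = m.values.std(axis=1, ddof=ddof)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"modality {m.name!r}: cell {bad[0]} has zero feature variance"
        )
    out = (m.values - m.values.mean(axis=1, keepdims=True)) / sd[:, None]
    return replace(m, values=out)


def standardize_features(m: ModalityMatrix, ddof: int = 0) -> ModalityMatrix:
    """Per-feature (column) standardization; the more common convention,
    provided as a non-default alternative."""
    sd = m.values.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"modality {m.name!r}: feature {m.feature_names[bad[0]]!r} is constant"
        )
    out = (m.values - m.values.mean(axis=0)) / sd
    return replace(m, values=out)


def normalize_log1p(m: ModalityMatrix) -> ModalityMatrix:
    """Median-total normalization followed by log1p.

    Each cell's counts are scaled so its total equals the median of the
    pre-scaling totals; all-zero cells are left as zeros with a warning.
    """
    if (m.values < 0).any():
        raise ValueError(f"modality {m.name!r}: negative counts")
    totals = m.values.sum(axis=1)
    median = np.median(totals[totals > 0]) if (totals > 0).any() else 0.0
    out = m.values.copy()
    nz = totals > 0
    if (~nz).any():
        logger.warning(
            "modality %r: %d all-zero cells left unscaled", m.name, int((~nz).sum())
        )
    out[nz] = out[nz] * (median / totals[nz])[:, None]
    return replace(m, values=np.log1p(out))


def binarize(m: ModalityMatrix) -> ModalityMatrix:
    return replace(m, values=(m.values != 0).astype(np.float64), is_binary=True)


def select_top_variable(m: ModalityMatrix, n_top: int) -> ModalityMatrix:
    """Keep the ``n_top`` highest-variance columns, preserving column order."""
    if not 0 < n_top <= m.n_features:
        raise ValueError(
            f"n_top must be in [1, {m.n_features}], got {n_top}"
        )
    var = m.values.var(axis=0)
    keep = np.sort(np.argsort(var, kind="stable")[::-1][:n_top])
    return replace(
        m,
        values=m.values[:, keep],
        feature_names=[m.feature_names[j] for j in keep],
    )


def split_folds(
    d: MultiModalDataset, k: int, mode: str = "random", seed: int = 0
) -> FoldSplit:
    """Partition cells into k folds — balanced random, or whole batches."""
    n = d.n_cells
    if k < 2:
        raise ValueError("k must be ≥ 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells n={n}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if mode == "random":
        perm = rng.permutation(n)
        # balanced: fold sizes differ by at most one
        assignment[perm] = (np.arange(n) % k) + 1
    elif mode == "by_batch":
        if d.batch_ids is None:
            raise ValueError("by_batch splitting requires batch_ids")
        batches = np.unique(d.batch_ids)
        if len(batches) < k:
            raise ValueError(f"need ≥ {k} batches, found {len(batches)}")
        order = rng.permutation(len(batches))
        fold_of_batch = {
            batches[b]: (i % k) + 1 for i, b in enumerate(order)
        }
        for i, b in enumerate(d.batch_ids):
            assignment[i] = fold_of_batch[b]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return FoldSplit(fold_assignment=assignment, seed=seed)
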