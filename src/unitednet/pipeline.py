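"""End-to-end runs with a reproducibility manifest.

``run_end_to_end`` executes preprocess → train → group inference →
cross-modal prediction → explain → evaluate from one configuration
mapping, writing every artifact plus a manifest that records the config
snapshot, seed, package versions, input checksums, and output paths.
"""

from __future__ import annotations

import hashlib
import json
import time
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import __version__
from .data import (
    MultiModalDataset,
    binarize,
    load_dataset,
    normalize_log1p,
    save_modality,
    select_top_variable,
    standardize_cells,
)
from .explain import group_feature_relevance
from .metrics import ari
from .network import ModelConfig
from .simulate import (
    DYNGEN_LIKE,
    MUSE_LIKE,
    GeneratorSpec,
    simulate_batches,
    simulate_multimodal,
    simulate_spatial,
)
from .training import infer_groups, predict_cross_modal, train

__all__ = ["RunManifest", "run_end_to_end", "build_dataset", "PRESETS"]


def _preset_spec(name: str, seed: int) -> GeneratorSpec:
    base = {
        "dyngen4": DYNGEN_LIKE,
        "muse2": MUSE_LIKE,
        "batched": GeneratorSpec(
            n_cells=800, n_groups=4, n_modalities=2, n_features=(60, 60)
        ),
        "spatial": GeneratorSpec(
            n_cells=400, n_groups=4, n_modalities=2, n_features=(50, 50)
        ),
    }[name]
    return GeneratorSpec(**{**base.__dict__, "seed": seed})


PRESETS = ("dyngen4", "muse2", "batched", "spatial")


def simulate_preset(name: str, seed: int = 0) -> MultiModalDataset:
    spec = _preset_spec(name, seed)
    if name == "batched":
        return simulate_batches(spec, n_batches=5, shift=2.0)
    if name == "spatial":
        return simulate_spatial(spec)
    return simulate_multimodal(spec)


class RunManifest:
    def __init__(self, out_dir: Path, config: dict, seed: int):
        self.path = Path(out_dir) / "manifest.json"
        self.data = {
            "package_version": __version__,
            "seed": seed,
            "config": config,
            "input_checksums": {},
            "outputs": {},
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "finished": None,
            "status": "running",
        }
        self.write()

    def checksum_inputs(self, paths: dict[str, str]) -> None:
        for name, p in paths.items():
            digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()
            self.data["input_checksums"][name] = digest

    def add_output(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.data["outputs"][name] = {"path": str(path), "sha256": digest}
        self.write()

    def finalize(self, status: str = "ok") -> None:
        self.data["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.data["status"] = status
        self.write()

    def write(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=2, default=str))


def _preprocess(dataset: MultiModalDataset, steps: dict) -> MultiModalDataset:
    mods = []
    for m in dataset.modalities:
        plan = steps.get(m.name, {})
        if plan.get("log1p_median"):
            m = normalize_log1p(m)
        if plan.get("binarize"):
            m = binarize(m)
        if plan.get("hvg"):
            m = select_top_variable(m, int(plan["hvg"]))
        if plan.get("standardize_cells"):
            m = standardize_cells(m)
        mods.append(m)
    return MultiModalDataset(
        modalities=mods,
        labels=dataset.labels,
        batch_ids=dataset.batch_ids,
        coords=dataset.coords,
        cell_ids=dataset.cell_ids,
        marker_truth=dataset.marker_truth,
    )


def build_dataset(config: dict) -> MultiModalDataset:
    """Dataset from a config mapping: either a simulation preset or
    per-modality file paths."""
    data_cfg = config.get("data", {})
    if "preset" in data_cfg:
        ds = simulate_preset(data_cfg["preset"], seed=int(data_cfg.get("seed", 0)))
    elif "modalities" in data_cfg:
        ds = load_dataset(
            data_cfg["modalities"],
            labels_path=data_cfg.get("labels"),
            coords_path=data_cfg.get("coords"),
        )
    else:
        raise ValueError("config['data'] must give a 'preset' or 'modalities'")
    if "preprocess" in config:
        ds = _preprocess(ds, config["preprocess"])
    return ds


def _validate(config: dict) -> ModelConfig:
    model_cfg = dict(config.get("model", {}))
    mode = model_cfg.get("mode", "unsupervised")
    if mode == "unsupervised" and "n_groups" not in model_cfg:
        raise ValueError("unsupervised mode requires model.n_groups (K) in the config")
    return ModelConfig(**model_cfg)


def run_end_to_end(config: dict, out_dir: str | Path) -> dict:
    """Run the whole pipeline; returns a summary dict.

    Any stage failure raises with the stage name; the manifest then
    records the partial status.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = _validate(config)
    manifest = RunManifest(out_dir, config, seed=cfg.seed)
    stage = "setup"
    try:
        stage = "load"
        dataset = build_dataset(config)
        if "modalities" in config.get("data", {}):
            manifest.checksum_inputs(config["data"]["modalities"])

        stage = "train"
        model = train(dataset, cfg)
        ckpt = out_dir / "model.ckpt.npz"
        model.save(ckpt)
        manifest.add_output("model", ckpt)
        model.train_state.write_log(out_dir / "training_log.csv")
        manifest.add_output("training_log", out_dir / "training_log.csv")

        stage = "infer_groups"
        labels, alpha = infer_groups(model, dataset)
        label_df = pd.DataFrame(
            alpha, columns=[f"alpha_{k+1}" for k in range(alpha.shape[1])]
        )
        label_df.insert(0, "group", labels)
        label_df.insert(
            0,
            "cell_id",
            dataset.cell_ids or [f"cell{i}" for i in range(dataset.n_cells)],
        )
        labels_path = out_dir / "labels.csv"
        label_df.to_csv(labels_path, index=False)
        manifest.add_output("labels", labels_path)

        stage = "predict"
        pairs = config.get("prediction_pairs") or [
            [a, b]
            for v1, v2 in combinations(range(model.n_modalities), 2)
            for a, b in (
                (model.modality_names[v1], model.modality_names[v2]),
                (model.modality_names[v2], model.modality_names[v1]),
            )
        ]
        pred_summary = {}
        for src, tgt in pairs:
            res = predict_cross_modal(model, dataset, src, tgt)
            path = out_dir / f"prediction_{src}_to_{tgt}.csv"
            save_modality(
                dataset.modality(tgt).__class__(
                    name=tgt,
                    values=res.predicted,
                    feature_names=dataset.modality(tgt).feature_names,
                ),
                path,
                dataset.cell_ids or [f"cell{i}" for i in range(dataset.n_cells)],
            )
            manifest.add_output(f"prediction_{src}_to_{tgt}", path)
            pred_summary[f"{src}->{tgt}"] = res.metrics["overall"]

        stage = "explain"
        n_top = int(config.get("explain", {}).get("n_top", 7))
        relevance = group_feature_relevance(model, dataset, n_top=n_top)
        rel_path = out_dir / "relevance.csv"
        relevance.table.to_csv(rel_path, index=False)
        manifest.add_output("relevance", rel_path)

        stage = "evaluate"
        summary = {
            "prediction_overall": pred_summary,
            "eta": model.eta.tolist(),
            "n_cells": dataset.n_cells,
        }
        if dataset.labels is not None:
            summary["ari"] = ari(labels, dataset.labels)
        metrics_path = out_dir / "metrics.json"
        metrics_path.write_text(json.dumps(summary, indent=2))
        manifest.add_output("metrics", metrics_path)
        manifest.finalize("ok")
        return summary
    except Exception as exc:
        manifest.finalize(f"failed at stage {stage}: {exc}")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
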