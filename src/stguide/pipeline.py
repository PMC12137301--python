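"""End-to-end orchestration: preprocess -> graphs -> train -> transfer -> evaluate.

A run directory is self-describing: it holds the resolved configuration,
a stage-by-stage manifest, loss traces, embeddings, predictions and (when
query truth is available) metrics, all in standard text/HDF5 formats.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import MultiSliceDataset
from .losses import LossWeights
from .model import StGuide, StGuideResults, TrainConfig

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_all", "resolve_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "model": {
        "n_top_hvgs": 5000,
        "avg_k": 5,
        "mnn_k": 5,
        "pca_dim": 50,
        "hidden_dim": 512,
        "latent_dim": 10,
        "n_heads": 3,
    },
    "train": {
        "epochs_phase1": 800,
        "epochs_phase2": 800,
        "learning_rate": 2e-3,
        "weight_decay": 1e-4,
        "seed": 0,
        "alpha": 10.0,
        "beta": 10.0,
        "eta": 10.0,
        "theta": 10.0,
        "warm_start_phase2": False,
    },
    "transfer": {"k": 1},
}


def resolve_config(overrides: dict | None = None) -> dict:
    """Deep-merge user overrides onto the documented defaults."""
    config = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in (overrides or {}).items():
        if section not in config:
            raise KeyError(f"unknown config section {section!r}")
        for key, val in values.items():
            if key not in config[section]:
                raise KeyError(f"unknown config key {section}.{key}")
            config[section][key] = val
    return config


def _train_config(train: dict) -> TrainConfig:
    return TrainConfig(
        epochs_phase1=train["epochs_phase1"],
        epochs_phase2=train["epochs_phase2"],
        learning_rate=train["learning_rate"],
        weight_decay=train["weight_decay"],
        seed=train["seed"],
        weights=LossWeights(
            alpha=train["alpha"],
            beta=train["beta"],
            eta=train["eta"],
            theta=train["theta"],
        ),
        warm_start_phase2=train["warm_start_phase2"],
    )


class RunManifest:
    """Per-stage status record, written atomically after every stage."""

    def __init__(self, out_dir: Path, config: dict, seed: int):
        from . import __version__

        self.path = Path(out_dir) / "manifest.json"
        self.data = {
            "version": __version__,
            "seed": seed,
            "config": config,
            "stages": {},
            "outputs": {},
        }

    def record(self, stage: str, status: str, seconds: float, **extra) -> None:
        self.data["stages"][stage] = {
            "status": status,
            "seconds": round(seconds, 3),
            **extra,
        }
        tmp = self.path.with_suffix(".json.tmp")
        tmp.write_text(json.dumps(self.data, indent=2))
        tmp.replace(self.path)


def _dataset_hashes(dataset: MultiSliceDataset) -> dict:
    out = {}
    for s in dataset.slices:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(s.expression).tobytes())
        h.update(np.ascontiguousarray(s.coords).tobytes())
        out[s.slice_id] = h.hexdigest()[:16]
    return out


def run_all(
    dataset: MultiSliceDataset,
    out_dir,
    config: dict | None = None,
) -> tuple[RunManifest, StGuideResults]:
    """Execute every stage on a dataset, writing artifacts to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = resolve_config(config)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    manifest = RunManifest(out_dir, cfg, cfg["train"]["seed"])
    manifest.data["inputs"] = _dataset_hashes(dataset)

    t0 = time.perf_counter()
    try:
        for s in dataset.reference_slices:
            if s.labels is None:  # pragma: no cover - guarded by SliceData
                raise ValueError(f"reference slice {s.slice_id!r} lacks labels")
        manifest.record("validate", "ok", time.perf_counter() - t0)
    except Exception:
        manifest.record("validate", "failed", time.perf_counter() - t0)
        raise

    t0 = time.perf_counter()
    try:
        model = StGuide(dataset, **cfg["model"])
        manifest.record(
            "preprocess+graph",
            "ok",
            time.perf_counter() - t0,
            n_common_genes=len(model.genes),
            edges_ref=len(model.graph_ref.edges),
            edges_all=len(model.graph_all.edges),
        )
    except Exception:
        manifest.record("preprocess+graph", "failed", time.perf_counter() - t0)
        raise
    model.graph_ref.to_tsv(out_dir / "edges_reference.tsv")
    model.graph_all.to_tsv(out_dir / "edges_all.tsv")

    t0 = time.perf_counter()
    try:
        results = model.fit(_train_config(cfg["train"]))
        manifest.record("train", "ok", time.perf_counter() - t0)
    except Exception:
        manifest.record("train", "failed", time.perf_counter() - t0)
        raise
    results.trace_phase1.to_csv(out_dir / "loss_phase1.csv", index=False)
    results.trace_phase2.to_csv(out_dir / "loss_phase2.csv", index=False)
    results.network_phase1.save(out_dir / "checkpoint_phase1.npz")
    results.network_phase2.save(out_dir / "checkpoint_phase2.npz")
    np.savez(
        out_dir / "embeddings.npz",
        z_r=results.z_r,
        z_r_prime=results.z_r_prime,
        z_q=results.z_q,
    )
    cats = model.label_categories
    ref_rows = []
    for g, code in enumerate(model.y_ref):
        sid, local = model.map_ref.locate(g)
        ref_rows.append(
            {"slice_id": sid, "spot_id": local, "code": int(code), "label": cats[code]}
        )
    pd.DataFrame(ref_rows).to_csv(out_dir / "reference_labels.csv", index=False)
    qrows = []
    n_ref = results.z_r.shape[0]
    for g in range(results.z_q.shape[0]):
        sid, local = model.map_all.locate(n_ref + g)
        qrows.append({"slice_id": sid, "spot_id": local})
    pd.DataFrame(qrows).to_csv(out_dir / "query_spots.csv", index=False)

    t0 = time.perf_counter()
    try:
        preds = results.predictions_frame(k=cfg["transfer"]["k"])
        preds.to_csv(out_dir / "predictions.csv", index=False)
        manifest.record("transfer", "ok", time.perf_counter() - t0, n_query=len(preds))
    except Exception:
        manifest.record("transfer", "failed", time.perf_counter() - t0)
        raise
    manifest.data["outputs"]["predictions"] = "predictions.csv"

    t0 = time.perf_counter()
    if dataset.L > 0 and all(
        s.slice_id in dataset.hidden_labels for s in dataset.query_slices
    ):
        report = results.evaluate(k=cfg["transfer"]["k"])
        (out_dir / "metrics.json").write_text(json.dumps(report.as_dict(), indent=2))
        manifest.record(
            "evaluate",
            "ok",
            time.perf_counter() - t0,
            accuracy=report.accuracy,
            ari=report.ari,
            nmi=report.nmi,
        )
    else:
        manifest.record("evaluate", "skipped (no query truth)", 0.0)
    (out_dir / "summary.txt").write_text(results.summary() + "\n")
    return manifest, results
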