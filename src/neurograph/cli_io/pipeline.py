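"""End-to-end pipeline: read cohort -> FC -> binarize -> connectivity ->
train/evaluate under the selected protocol -> artifacts on disk."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ..dgcnn import DGCNNClassifier, DGCNNConfig, train_model
from ..evaluation import (
    fold_report,
    holdout_split,
    kfold_cv,
    leave_one_site_out,
)
from ..fc_network import MDD, NC, BrainGraph, build_graph, pearson_fc, threshold_binarize
from ..graph_connectivity import connectivity_table
from .io import load_yaml, read_cohort, save_checkpoint, save_yaml
from .logging import log_event, setup_run_logger

PROTOCOLS = ("holdout", "kfold", "loso")


@dataclass(frozen=True)
class PipelineConfig:
    manifest: str
    out_dir: str
    threshold: float = 0.3
    absolute: bool = False
    protocol: str = "kfold"
    kfolds: int = 10
    train_fraction: float = 0.9
    split_seed: int = 0
    connectivity_thresholds: tuple[float, ...] = (0.2, 0.3, 0.4)
    dgcnn: DGCNNConfig = field(default_factory=DGCNNConfig)
    verbose: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")
        object.__setattr__(
            self, "connectivity_thresholds", tuple(float(t) for t in self.connectivity_thresholds)
        )

    def to_dict(self) -> dict:
        return {
            "manifest": str(self.manifest),
            "out_dir": str(self.out_dir),
            "threshold": self.threshold,
            "absolute": self.absolute,
            "protocol": self.protocol,
            "kfolds": self.kfolds,
            "train_fraction": self.train_fraction,
            "split_seed": self.split_seed,
            "connectivity_thresholds": list(self.connectivity_thresholds),
            "dgcnn": self.dgcnn.to_dict(),
            "verbose": self.verbose,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "dgcnn" in d and isinstance(d["dgcnn"], dict):
            d["dgcnn"] = DGCNNConfig.from_dict(d["dgcnn"])
        if "connectivity_thresholds" in d:
            d["connectivity_thresholds"] = tuple(d["connectivity_thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(load_yaml(path))


def build_graphs(cohort, threshold: float, absolute: bool = False) -> list[BrainGraph]:
    """FC + binarization + graph assembly for every subject."""
    graphs = []
    for ts in cohort:
        fc = pearson_fc(ts)
        adj = threshold_binarize(fc, threshold, absolute=absolute)
        graphs.append(build_graph(fc, adj))
    return graphs


def _cohort_fingerprint(cohort) -> str:
    h = hashlib.sha256()
    for ts in sorted(cohort, key=lambda t: t.subject_id):
        h.update(ts.subject_id.encode())
        h.update(ts.label.encode())
        h.update(ts.site_id.encode())
        h.update(np.ascontiguousarray(ts.signals).tobytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage; returns a dict of output artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup_run_logger(out / "run.log", verbose=config.verbose)
    outputs: dict[str, Path] = {"log": out / "run.log"}
    log_event("info", "pipeline", "start")

    try:
        log_event("info", "read", f"loading cohort from {config.manifest}")
        cohort = read_cohort(config.manifest)
        log_event("info", "read", f"loaded {len(cohort)} subjects")
    except Exception as exc:
        log_event("error", "read", str(exc))
        raise RuntimeError(f"stage 'read' failed: {exc}") from exc

    try:
        log_event("info", "connectivity", "computing per-threshold connectivity table")
        fcs = [pearson_fc(ts) for ts in cohort]
        table = connectivity_table(fcs, config.connectivity_thresholds, absolute=config.absolute)
        conn_path = out / "connectivity.csv"
        table.to_csv(conn_path, index=False)
        outputs["connectivity"] = conn_path
    except Exception as exc:
        log_event("error", "connectivity", str(exc))
        raise RuntimeError(f"stage 'connectivity' failed: {exc}") from exc

    try:
        log_event("info", "graphs", f"binarizing at threshold {config.threshold}")
        graphs = build_graphs(cohort, config.threshold, absolute=config.absolute)
    except Exception as exc:
        log_event("error", "graphs", str(exc))
        raise RuntimeError(f"stage 'graphs' failed: {exc}") from exc

    try:
        log_event("info", "evaluate", f"protocol={config.protocol}")
        metrics_path = out / "metrics.csv"
        if config.protocol == "holdout":
            train, test = holdout_split(
                graphs, train_fraction=config.train_fraction, seed=config.split_seed
            )
            params, history = train_model(train, test, config.dgcnn)
            history.to_dataframe().to_csv(out / "history.csv", index=False)
            outputs["history"] = out / "history.csv"
            save_checkpoint(out / "checkpoint.npz", params, config.dgcnn)
            outputs["checkpoint"] = out / "checkpoint.npz"
            clf = DGCNNClassifier(config.dgcnn)
            clf.params = params
            scores = clf.predict_proba(test)
            preds = [MDD if s >= 0.5 else NC for s in scores]
            report = fold_report(preds, [g.label for g in test], scores)
            import pandas as pd

            pd.DataFrame([{"fold": "holdout", **report.to_dict()}]).to_csv(
                metrics_path, index=False
            )
        elif config.protocol == "kfold":
            result = kfold_cv(graphs, config.dgcnn, k=config.kfolds, seed=config.split_seed)
            result.to_dataframe().to_csv(metrics_path, index=False)
        else:  # loso
            result = leave_one_site_out(graphs, config.dgcnn)
            result.to_dataframe().to_csv(metrics_path, index=False)
        outputs["metrics"] = metrics_path
    except Exception as exc:
        log_event("error", "evaluate", str(exc))
        raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "n_subjects": len(cohort),
        "cohort_sha256": _cohort_fingerprint(cohort),
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    run_manifest = out / "run_manifest.json"
    run_manifest.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["run_manifest"] = run_manifest
    save_yaml(config.to_dict(), out / "config.yaml")
    outputs["config"] = out / "config.yaml"
    log_event("info", "pipeline", "end")
    return outputs
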