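"""Readers and writers for cohorts, matrices, configs, and checkpoints.

On-disk layout: a cohort is a manifest CSV (subject_id, path, label,
site_id) whose paths point at per-subject TSV signal matrices (n_rois rows,
T columns, no header). Node indices are 0-based in every output file.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ..fc_network import BinaryAdjacency, FCMatrix, ROITimeSeries, normalize_label
from ..dgcnn.config import DGCNNConfig
from ..dgcnn.model import ModelParams

MANIFEST_COLUMNS = ("subject_id", "path", "label", "site_id")


def write_cohort(cohort: Sequence[ROITimeSeries], out_dir: str | Path) -> Path:
    """Write per-subject signal TSVs plus a manifest CSV; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig_dir = out / "signals"
    sig_dir.mkdir(exist_ok=True)
    rows = []
    for ts in cohort:
        rel = Path("signals") / f"{ts.subject_id}.tsv"
        np.savetxt(out / rel, ts.signals, delimiter="\t", fmt="%.17g")
        rows.append(
            {"subject_id": ts.subject_id, "path": str(rel), "label": ts.label, "site_id": ts.site_id}
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


def _load_signals(path: Path, orientation: str) -> np.ndarray:
    sig = np.loadtxt(path, delimiter="\t", ndmin=2)
    if orientation == "time-by-rois":
        return sig.T
    if orientation == "rois-by-time":
        return sig
    # auto: files are stored rois-by-time; a square matrix is ambiguous
    if sig.shape[0] == sig.shape[1]:
        raise ValueError(
            f"{path}: square signal matrix is ambiguous; pass orientation explicitly"
        )
    return sig


def read_cohort(
    manifest_path: str | Path, orientation: str = "auto"
) -> list[ROITimeSeries]:
    """Load and validate every subject listed in a manifest CSV.

    ``orientation`` is one of ``auto`` (rois-by-time unless the matrix is
    square, which errors), ``rois-by-time``, or ``time-by-rois``.
    """
    if orientation not in ("auto", "rois-by-time", "time-by-rois"):
        raise ValueError(f"unknown orientation {orientation!r}")
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = manifest_path.parent
    cohort: list[ROITimeSeries] = []
    for _, row in df.iterrows():
        sid = row["subject_id"]
        if pd.isna(sid) or pd.isna(row["path"]) or pd.isna(row["label"]):
            raise ValueError(f"malformed manifest row for subject {sid!r}")
        path = Path(row["path"])
        if not path.is_absolute():
            path = base / path
        if not path.exists():
            raise FileNotFoundError(f"subject {sid}: signal file {path} not found")
        try:
            signals = _load_signals(path, orientation)
            ts = ROITimeSeries(
                subject_id=str(sid),
                site_id="" if pd.isna(row["site_id"]) else str(row["site_id"]),
                label=normalize_label(row["label"]),
                signals=signals,
            )
        except ValueError as exc:
            raise ValueError(f"subject {sid}: {exc}") from exc
        cohort.append(ts)
    shapes = {ts.signals.shape[0] for ts in cohort}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent ROI counts across subjects: {sorted(shapes)}")
    return cohort


def write_matrix_csv(values: np.ndarray, path: str | Path) -> None:
    """Square matrix as headerless CSV."""
    np.savetxt(path, np.asarray(values), delimiter=",", fmt="%.17g")


def read_matrix_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_edge_list(adj: BinaryAdjacency, path: str | Path, fc: FCMatrix | None = None) -> None:
    """Undirected edge list TSV (node_i, node_j, weight), 0-based indices.

    The weight column is the FC correlation when ``fc`` is given, else 1.
    """
    rows_i, rows_j = np.nonzero(np.triu(adj.entries, k=1))
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\tweight\n")
        for i, j in zip(rows_i, rows_j):
            w = fc.values[i, j] if fc is not None else 1.0
            fh.write(f"{i}\t{j}\t{w:.17g}\n")


def save_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_checkpoint(path: str | Path, params: ModelParams, config: DGCNNConfig) -> None:
    """Single-file archive of all parameter arrays plus the serialized config."""
    arrays = dict(params)
    arrays["__config__"] = np.frombuffer(
        json.dumps(config.to_dict()).encode("utf-8"), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path: str | Path) -> tuple[ModelParams, DGCNNConfig]:
    with np.load(path) as data:
        config = DGCNNConfig.from_dict(
            json.loads(bytes(data["__config__"].tolist()).decode("utf-8"))
        )
        params = {k: data[k] for k in data.files if k != "__config__"}
    return params, config
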