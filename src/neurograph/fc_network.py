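"""Functional-connectivity network construction.

Turns per-subject ROI time series into Pearson correlation matrices,
thresholded binary adjacency matrices, and graph objects (binary adjacency
plus continuous node features) ready for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MDD = "MDD"
NC = "NC"
LABELS = (MDD, NC)

_SYM_TOL = 1e-8


def normalize_label(value: str) -> str:
    """Map a label string to the canonical ``MDD``/``NC`` spelling.

    Case-insensitive; raises ``ValueError`` for anything else.
    """
    up = str(value).strip().upper()
    if up not in LABELS:
        raise ValueError(f"unknown label {value!r}; expected one of {LABELS}")
    return up


@dataclass(frozen=True)
class ROITimeSeries:
    """One subject's ROI-averaged signal matrix (n_rois x T) with metadata."""

    subject_id: str
    site_id: str
    label: str
    signals: np.ndarray

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, dtype=np.float64)
        if sig.ndim != 2:
            raise ValueError(
                f"subject {self.subject_id}: signals must be 2-D, got ndim={sig.ndim}"
            )
        n_rois, t = sig.shape
        if n_rois < 2:
            raise ValueError(f"subject {self.subject_id}: need at least 2 ROIs, got {n_rois}")
        if t < 3:
            raise ValueError(f"subject {self.subject_id}: need at least 3 time points, got {t}")
        if not np.isfinite(sig).all():
            raise ValueError(f"subject {self.subject_id}: signals contain non-finite values")
        variances = sig.var(axis=1)
        dead = np.flatnonzero(variances == 0.0)
        if dead.size:
            raise ValueError(
                f"subject {self.subject_id}: ROI {int(dead[0])} has zero variance; "
                "Pearson correlation is undefined"
            )
        object.__setattr__(self, "signals", sig)
        object.__setattr__(self, "label", normalize_label(self.label))

    @property
    def n_rois(self) -> int:
        return self.signals.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signals.shape[1]


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric Pearson correlation matrix with subject metadata."""

    values: np.ndarray
    subject_id: str = ""
    site_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError(f"FC matrix must be square, got shape {vals.shape}")
        if not np.allclose(vals, vals.T, atol=_SYM_TOL):
            raise ValueError("FC matrix must be symmetric")
        if vals.min() < -1.0 - _SYM_TOL or vals.max() > 1.0 + _SYM_TOL:
            raise ValueError("FC entries must lie in [-1, 1]")
        if not np.allclose(np.diag(vals), 1.0, atol=_SYM_TOL):
            raise ValueError("FC diagonal entries must equal 1")
        object.__setattr__(self, "values", vals)
        if self.label is not None:
            object.__setattr__(self, "label", normalize_label(self.label))

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BinaryAdjacency:
    """0/1 adjacency from thresholding an FC matrix; no self-loops."""

    entries: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        ent = np.asarray(self.entries)
        if ent.ndim != 2 or ent.shape[0] != ent.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {ent.shape}")
        if not np.isin(ent, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        ent = ent.astype(np.uint8)
        if (ent != ent.T).any():
            raise ValueError("adjacency must be symmetric")
        if np.diag(ent).any():
            raise ValueError("adjacency must have a zero diagonal (no self-loops)")
        object.__setattr__(self, "entries", ent)

    @property
    def n_nodes(self) -> int:
        return self.entries.shape[0]

    @property
    def edge_count(self) -> int:
        """Number of undirected edges."""
        return int(self.entries.sum()) // 2


@dataclass(frozen=True)
class BrainGraph:
    """Classifier input: binary adjacency + continuous node features + label."""

    adjacency: BinaryAdjacency
    node_features: np.ndarray
    label: str | None = None
    site_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        feats = np.asarray(self.node_features, dtype=np.float64)
        if feats.ndim != 2:
            raise ValueError("node_features must be 2-D (n_nodes x d)")
        if feats.shape[0] != self.adjacency.n_nodes:
            raise ValueError(
                f"node_features has {feats.shape[0]} rows but adjacency has "
                f"{self.adjacency.n_nodes} nodes"
            )
        object.__setattr__(self, "node_features", feats)
        if self.label is not None:
            object.__setattr__(self, "label", normalize_label(self.label))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.n_nodes


def pearson_fc(ts: ROITimeSeries) -> FCMatrix:
    """Pearson correlation matrix across ROI rows of a subject's signals."""
    corr = np.corrcoef(ts.signals)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return FCMatrix(values=corr, subject_id=ts.subject_id, site_id=ts.site_id, label=ts.label)


def threshold_binarize(fc: FCMatrix, tau: float, absolute: bool = False) -> BinaryAdjacency:
    """Binarize an FC matrix: edge (i,j) iff i != j and corr(i,j) >= tau.

    The comparison is on the signed correlation by default; pass
    ``absolute=True`` to threshold |corr| instead. The boundary is inclusive.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {tau}")
    vals = np.abs(fc.values) if absolute else fc.values
    entries = (vals >= tau).astype(np.uint8)
    np.fill_diagonal(entries, 0)
    return BinaryAdjacency(entries=entries, threshold=float(tau))


def build_graph(
    fc: FCMatrix,
    adj: BinaryAdjacency,
    label: str | None = None,
    site_id: str | None = None,
    subject_id: str | None = None,
    binary_features: bool = False,
) -> BrainGraph:
    """Assemble a graph whose node features are rows of the FC matrix.

    With ``binary_features=True`` the binary adjacency rows are used as
    features instead of the continuous correlation profile.
    """
    if fc.values.shape != adj.entries.shape:
        raise ValueError(
            f"dimension mismatch: FC is {fc.values.shape}, adjacency is {adj.entries.shape}"
        )
    feats = adj.entries.astype(np.float64) if binary_features else fc.values.copy()
    return BrainGraph(
        adjacency=adj,
        node_features=feats,
        label=label if label is not None else fc.label,
        site_id=site_id if site_id is not None else fc.site_id,
        subject_id=subject_id if subject_id is not None else fc.subject_id,
    )
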