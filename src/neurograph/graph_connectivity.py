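"""Graph connectivity via the Warshall transitive-closure recursion.

Decides whether each thresholded brain network is connected and summarizes
a cohort by its connectivity ratio (connected count / unconnected count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fc_network import BinaryAdjacency, FCMatrix, threshold_binarize


@dataclass(frozen=True)
class ReachabilityMatrix:
    """Boolean reachability matrix R^(k) after the k-th Warshall pass."""

    entries: np.ndarray
    order: int

    def __post_init__(self) -> None:
        ent = np.asarray(self.entries, dtype=bool)
        if ent.ndim != 2 or ent.shape[0] != ent.shape[1]:
            raise ValueError(f"reachability matrix must be square, got {ent.shape}")
        object.__setattr__(self, "entries", ent)

    @property
    def n_nodes(self) -> int:
        return self.entries.shape[0]


def _adjacency_array(adj: BinaryAdjacency | np.ndarray) -> np.ndarray:
    if isinstance(adj, BinaryAdjacency):
        return adj.entries.astype(bool)
    arr = np.asarray(adj).astype(bool)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"adjacency must be square, got {arr.shape}")
    return arr


def warshall_closure(adj: BinaryAdjacency | np.ndarray) -> ReachabilityMatrix:
    """Reflexive-transitive closure by the Boolean Warshall recursion.

    R^(k)[i,j] = R^(k-1)[i,j] OR (R^(k-1)[i,k] AND R^(k-1)[k,j]); the inner
    i/j loops are vectorized, the pivot loop over k is the recursion itself.
    """
    arr = _adjacency_array(adj)
    n = arr.shape[0]
    reach = arr | np.eye(n, dtype=bool)
    for k in range(n):
        reach |= reach[:, k : k + 1] & reach[k : k + 1, :]
    return ReachabilityMatrix(entries=reach, order=n)


def is_connected(closure: ReachabilityMatrix | BinaryAdjacency | np.ndarray) -> bool:
    """True iff every ordered pair of distinct nodes is mutually reachable."""
    if not isinstance(closure, ReachabilityMatrix):
        closure = warshall_closure(closure)
    return bool(closure.entries.all())


def connectivity_ratio(graphs: Iterable[BinaryAdjacency | np.ndarray]) -> float:
    """(# connected graphs) / (# unconnected graphs) over a cohort.

    Returns ``math.inf`` when every graph is connected, so threshold sweeps
    always complete.
    """
    n_connected = 0
    n_unconnected = 0
    for g in graphs:
        if is_connected(g):
            n_connected += 1
        else:
            n_unconnected += 1
    total = n_connected + n_unconnected
    if total == 0:
        raise ValueError("connectivity_ratio requires a nonempty collection of graphs")
    if n_unconnected == 0:
        return math.inf
    return n_connected / n_unconnected


def connectivity_table(
    fcs: Sequence[FCMatrix],
    thresholds: Sequence[float],
    absolute: bool = False,
) -> pd.DataFrame:
    """Per-threshold connectivity summary for a cohort of FC matrices.

    One row per threshold: total connected/unconnected counts and ratio,
    plus per-label ratios and mean edge counts when labels are attached.
    """
    if len(fcs) == 0:
        raise ValueError("connectivity_table requires a nonempty cohort")
    labels = sorted({fc.label for fc in fcs if fc.label is not None})
    rows = []
    for tau in thresholds:
        adjs = [threshold_binarize(fc, tau, absolute=absolute) for fc in fcs]
        connected = np.array([is_connected(a) for a in adjs])
        edges = np.array([a.edge_count for a in adjs], dtype=float)
        n_conn = int(connected.sum())
        n_unconn = len(adjs) - n_conn
        row: dict[str, object] = {
            "threshold": float(tau),
            "n_connected": n_conn,
            "n_unconnected": n_unconn,
            "connectivity_ratio": math.inf if n_unconn == 0 else n_conn / n_unconn,
            "mean_edges": float(edges.mean()),
        }
        for lab in labels:
            mask = np.array([fc.label == lab for fc in fcs])
            n_c = int(connected[mask].sum())
            n_u = int(mask.sum()) - n_c
            row[f"connectivity_ratio_{lab}"] = math.inf if n_u == 0 else n_c / n_u
            row[f"mean_edges_{lab}"] = float(edges[mask].mean())
        rows.append(row)
    return pd.DataFrame(rows)
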