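"""Forward and backward passes of the graph classifier, in plain NumPy.

The network: stacked graph convolutions ``Z_out = tanh(D^-1 (A+I) Z_in W)``
whose outputs are concatenated channel-wise, sort-pooled to a fixed number
of rows, then read by a 1-D convolutional head (conv -> max-pool -> conv),
a dense layer with dropout, and a 2-way softmax. Gradients are derived
analytically layer by layer so training needs no autodiff framework.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..fc_network import MDD, NC, BinaryAdjacency, BrainGraph
from .config import DGCNNConfig

ModelParams = dict[str, np.ndarray]


@dataclass(frozen=True)
class Prediction:
    """Class-probability pair and the implied hard label."""

    p_nc: float
    p_mdd: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_nc <= 1.0 and 0.0 <= self.p_mdd <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.p_nc + self.p_mdd - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")

    @property
    def label(self) -> str:
        return MDD if self.p_mdd >= self.p_nc else NC


def propagation_matrix(adj: BinaryAdjacency | np.ndarray) -> np.ndarray:
    """Row-normalized propagation operator D^-1 (A + I)."""
    a = adj.entries if isinstance(adj, BinaryAdjacency) else np.asarray(adj)
    a_tilde = a.astype(np.float64) + np.eye(a.shape[0])
    deg = a_tilde.sum(axis=1)
    return a_tilde / deg[:, None]


def graph_conv_layer(
    adj: BinaryAdjacency | np.ndarray,
    features: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """One degree-normalized graph convolution: tanh(D^-1 (A+I) X W)."""
    feats = np.asarray(features, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    s = propagation_matrix(adj)
    if feats.ndim != 2 or feats.shape[0] != s.shape[0]:
        raise ValueError(
            f"features shape {feats.shape} inconsistent with {s.shape[0]} nodes"
        )
    if w.ndim != 2 or w.shape[0] != feats.shape[1]:
        raise ValueError(f"weights shape {w.shape} inconsistent with features {feats.shape}")
    return np.tanh(s @ feats @ w)


def sort_order(stacked_features: np.ndarray) -> np.ndarray:
    """Node order used by sort-pooling.

    Descending by the last channel; ties broken by the preceding channels
    right-to-left, then by node index (lexsort is stable).
    """
    z = np.asarray(stacked_features, dtype=np.float64)
    keys = tuple(-z[:, c] for c in range(z.shape[1]))
    return np.lexsort(keys)


def sort_pooling(stacked_features: np.ndarray, k: int) -> np.ndarray:
    """Sort node rows into the canonical order, truncate/pad to k rows."""
    z = np.asarray(stacked_features, dtype=np.float64)
    if z.ndim != 2 or z.shape[0] < 1:
        raise ValueError("stacked_features must be a nonempty 2-D matrix")
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sort_order(z)
    out = np.zeros((k, z.shape[1]), dtype=np.float64)
    m = min(k, z.shape[0])
    out[:m] = z[order[:m]]
    return out


def head_geometry(config: DGCNNConfig, k: int) -> tuple[int, int]:
    """(pooled length, second-conv output length) of the 1-D head."""
    pooled = (k - config.pool_width) // config.pool_stride + 1
    out2 = pooled - config.conv2_width + 1
    if pooled < 1 or out2 < 1:
        raise ValueError(
            f"sort-pooling size k={k} too small for the 1-D head "
            f"(pool width {config.pool_width}, conv width {config.conv2_width})"
        )
    return pooled, out2


def init_params(
    n_features: int, config: DGCNNConfig, rng: np.random.Generator, k: int
) -> ModelParams:
    """Glorot-uniform initialization of every trainable array."""

    def glorot(shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    params: ModelParams = {}
    c_in = n_features
    for i, c_out in enumerate(config.conv_channels):
        params[f"gc_{i}"] = glorot((c_in, c_out), c_in, c_out)
        c_in = c_out
    c_total = config.total_channels
    f1, f2, w2 = config.conv1_filters, config.conv2_filters, config.conv2_width
    pooled, out2 = head_geometry(config, k)
    params["conv1_w"] = glorot((c_total, f1), c_total, f1)
    params["conv1_b"] = np.zeros(f1)
    params["conv2_w"] = glorot((f1, w2, f2), f1 * w2, f2 * w2)
    params["conv2_b"] = np.zeros(f2)
    flat = out2 * f2
    params["dense1_w"] = glorot((flat, config.dense_width), flat, config.dense_width)
    params["dense1_b"] = np.zeros(config.dense_width)
    params["dense2_w"] = glorot((config.dense_width, 2), config.dense_width, 2)
    params["dense2_b"] = np.zeros(2)
    return params


def prepare_inputs(graphs: Sequence[BrainGraph]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack equal-size graphs into (S, X, y) arrays for batched passes."""
    if len(graphs) == 0:
        raise ValueError("empty graph collection")
    n = graphs[0].n_nodes
    d = graphs[0].node_features.shape[1]
    for g in graphs:
        if g.n_nodes != n or g.node_features.shape[1] != d:
            raise ValueError("all graphs in a batch must have identical dimensions")
    s = np.stack([propagation_matrix(g.adjacency) for g in graphs])
    x = np.stack([g.node_features for g in graphs])
    y = np.array([1 if g.label == MDD else 0 for g in graphs], dtype=np.int64)
    return s, x, y


def forward_batch(
    s: np.ndarray,
    x: np.ndarray,
    params: ModelParams,
    config: DGCNNConfig,
    k: int,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Batched forward pass; returns (probabilities (B,2), cache for backward)."""
    if train and config.dropout_rate > 0.0 and rng is None:
        raise ValueError("train-mode forward with dropout requires an rng")
    b, n, _ = x.shape
    cache: dict = {"s": s, "train": train}

    # graph convolutions, caching pre-activation inputs for backprop
    z = x
    gc_h, gc_out = [], []
    for i in range(len(config.conv_channels)):
        h = s @ z
        z = np.tanh(h @ params[f"gc_{i}"])
        gc_h.append(h)
        gc_out.append(z)
    cache["gc_h"], cache["gc_out"] = gc_h, gc_out
    z_cat = np.concatenate(gc_out, axis=2)  # (B, n, C)

    # sort-pooling per graph
    c_total = z_cat.shape[2]
    m = min(k, n)
    y_sorted = np.zeros((b, k, c_total))
    orders = np.empty((b, m), dtype=np.int64)
    for bi in range(b):
        order = sort_order(z_cat[bi])[:m]
        orders[bi] = order
        y_sorted[bi, :m] = z_cat[bi, order]
    cache["orders"], cache["n"], cache["m"] = orders, n, m
    cache["y_sorted"] = y_sorted

    # conv stage 1: width = stride = C, i.e. a per-row dense map
    t1_lin = y_sorted @ params["conv1_w"] + params["conv1_b"]
    t1 = np.maximum(t1_lin, 0.0)
    cache["t1_lin"] = t1_lin

    # max-pool along the row axis
    pooled, out2 = head_geometry(config, k)
    pw, ps = config.pool_width, config.pool_stride
    t1_win = np.lib.stride_tricks.sliding_window_view(t1, pw, axis=1)[:, ::ps]  # (B,p,F1,pw)
    pool_arg = t1_win.argmax(axis=3)
    p1 = t1_win.max(axis=3)
    cache["pool_arg"], cache["t1_shape"] = pool_arg, t1.shape

    # conv stage 2: width-5 1-D convolution over the pooled rows
    w2 = config.conv2_width
    win = np.lib.stride_tricks.sliding_window_view(p1, w2, axis=1)  # (B, L2, F1, w2)
    t2_lin = np.einsum("blcw,cwo->blo", win, params["conv2_w"]) + params["conv2_b"]
    t2 = np.maximum(t2_lin, 0.0)
    cache["win"], cache["t2_lin"], cache["p1_shape"] = win, t2_lin, p1.shape

    flat = t2.reshape(b, -1)
    d1_lin = flat @ params["dense1_w"] + params["dense1_b"]
    d1 = np.maximum(d1_lin, 0.0)
    cache["flat"], cache["d1_lin"] = flat, d1_lin

    # inverted dropout: scale at train time, identity at eval
    if train and config.dropout_rate > 0.0:
        keep = 1.0 - config.dropout_rate
        mask = (rng.random(d1.shape) < keep).astype(np.float64) / keep
    else:
        mask = np.ones_like(d1)
    d1_drop = d1 * mask
    cache["mask"], cache["d1_drop"] = mask, d1_drop

    logits = d1_drop @ params["dense2_w"] + params["dense2_b"]
    logits = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(logits)
    probs = exp / exp.sum(axis=1, keepdims=True)
    cache["probs"] = probs
    return probs, cache


def backward_batch(
    d_logits: np.ndarray, cache: dict, params: ModelParams, config: DGCNNConfig
) -> ModelParams:
    """Analytic gradients for every parameter given dLoss/dLogits."""
    grads: ModelParams = {}
    d1_drop, mask = cache["d1_drop"], cache["mask"]

    grads["dense2_w"] = d1_drop.T @ d_logits
    grads["dense2_b"] = d_logits.sum(axis=0)
    d_d1 = (d_logits @ params["dense2_w"].T) * mask
    d_d1_lin = d_d1 * (cache["d1_lin"] > 0)

    grads["dense1_w"] = cache["flat"].T @ d_d1_lin
    grads["dense1_b"] = d_d1_lin.sum(axis=0)
    d_flat = d_d1_lin @ params["dense1_w"].T

    b = d_flat.shape[0]
    t2_lin = cache["t2_lin"]
    d_t2_lin = d_flat.reshape(t2_lin.shape) * (t2_lin > 0)
    win = cache["win"]
    grads["conv2_w"] = np.einsum("blo,blcw->cwo", d_t2_lin, win)
    grads["conv2_b"] = d_t2_lin.sum(axis=(0, 1))
    d_win = np.einsum("blo,cwo->blcw", d_t2_lin, params["conv2_w"])
    d_p1 = np.zeros(cache["p1_shape"])
    l2 = d_win.shape[1]
    for wi in range(config.conv2_width):
        d_p1[:, wi : wi + l2, :] += d_win[:, :, :, wi]

    # max-pool backward: route gradient to the argmax position of each window
    pw, ps = config.pool_width, config.pool_stride
    pool_arg = cache["pool_arg"]  # (B, p, F1)
    d_t1 = np.zeros(cache["t1_shape"])
    p = pool_arg.shape[1]
    b_idx, p_idx, f_idx = np.meshgrid(
        np.arange(b), np.arange(p), np.arange(pool_arg.shape[2]), indexing="ij"
    )
    d_t1[b_idx, p_idx * ps + pool_arg, f_idx] += d_p1

    d_t1_lin = d_t1 * (cache["t1_lin"] > 0)
    y_sorted = cache["y_sorted"]
    grads["conv1_w"] = np.einsum("bkc,bkf->cf", y_sorted, d_t1_lin)
    grads["conv1_b"] = d_t1_lin.sum(axis=(0, 1))
    d_y = d_t1_lin @ params["conv1_w"].T

    # sort-pooling backward: scatter sorted-row gradients to original rows
    orders, n, m = cache["orders"], cache["n"], cache["m"]
    d_zcat = np.zeros((b, n, d_y.shape[2]))
    for bi in range(b):
        d_zcat[bi, orders[bi]] = d_y[bi, :m]

    # graph-conv backward through the channel-wise concatenation
    s = cache["s"]
    gc_h, gc_out = cache["gc_h"], cache["gc_out"]
    splits = np.cumsum([0] + list(config.conv_channels))
    d_from_above = 0.0
    for i in reversed(range(len(config.conv_channels))):
        d_zout = d_zcat[:, :, splits[i] : splits[i + 1]] + d_from_above
        d_zlin = d_zout * (1.0 - gc_out[i] ** 2)
        grads[f"gc_{i}"] = np.einsum("bnc,bno->co", gc_h[i], d_zlin)
        d_h = d_zlin @ params[f"gc_{i}"].T
        d_from_above = np.matmul(s.transpose(0, 2, 1), d_h)
    return grads


def bce_loss(p_positive: np.ndarray, labels: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy of positive-class probabilities.

    Probabilities are clipped to [eps, 1-eps] before the logarithm.
    """
    p = np.asarray(p_positive, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.size == 0:
        raise ValueError("bce_loss requires a nonempty batch")
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    pc = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))


def bce_loss_grad_logits(
    probs: np.ndarray, labels: np.ndarray, eps: float = 1e-7
) -> tuple[float, np.ndarray]:
    """(loss, dLoss/dLogits) for softmax outputs under the BCE loss.

    The gradient is consistent with the clipped forward value: it vanishes
    where the probability sits in the clipped region.
    """
    y = np.asarray(labels, dtype=np.float64)
    p1 = probs[:, 1]
    loss = bce_loss(p1, y, eps=eps)
    pc = np.clip(p1, eps, 1.0 - eps)
    inside = (p1 > eps) & (p1 < 1.0 - eps)
    d_p1 = np.where(inside, (-(y / pc) + (1.0 - y) / (1.0 - pc)) / y.size, 0.0)
    d_z1 = d_p1 * p1 * (1.0 - p1)  # softmax pair: dp1/dz1 = p1(1-p1), dp1/dz0 = -p1(1-p1)
    d_logits = np.stack([-d_z1, d_z1], axis=1)
    return loss, d_logits


def forward(
    graph: BrainGraph,
    params: ModelParams,
    config: DGCNNConfig,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> Prediction:
    """Single-graph forward pass; deterministic in eval mode."""
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    s, x, _ = prepare_inputs([graph])
    k = config.resolve_k(graph.n_nodes)
    probs, _ = forward_batch(s, x, params, config, k, train=(mode == "train"), rng=rng)
    return Prediction(p_nc=float(probs[0, 0]), p_mdd=float(probs[0, 1]), subject_id=graph.subject_id)


def predict(
    params: ModelParams, config: DGCNNConfig, graphs: Sequence[BrainGraph]
) -> list[Prediction]:
    """Eval-mode predictions for a list of graphs, order preserved."""
    if len(graphs) == 0:
        return []
    s, x, _ = prepare_inputs(graphs)
    k = config.resolve_k(graphs[0].n_nodes)
    probs, _ = forward_batch(s, x, params, config, k, train=False)
    return [
        Prediction(p_nc=float(p0), p_mdd=float(p1), subject_id=g.subject_id)
        for (p0, p1), g in zip(probs, graphs)
    ]
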