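"""Mini-batch Adam training of the graph classifier."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ..fc_network import MDD, BrainGraph
from .config import DGCNNConfig
from .model import (
    ModelParams,
    Prediction,
    bce_loss,
    bce_loss_grad_logits,
    backward_batch,
    forward_batch,
    head_geometry,
    init_params,
    prepare_inputs,
)


@dataclass
class TrainingHistory:
    """Per-epoch loss/accuracy records on the full train and validation sets."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "epoch": np.arange(1, self.n_epochs + 1),
            "train_loss": self.train_loss,
            "train_acc": self.train_acc,
        }
        if self.val_loss:
            data["val_loss"] = self.val_loss
            data["val_acc"] = self.val_acc
        return pd.DataFrame(data)


class _Adam:
    """Standard Adam update with bias correction."""

    def __init__(self, params: ModelParams, config: DGCNNConfig) -> None:
        self.lr = config.learning_rate
        self.b1, self.b2, self.eps = config.adam_beta1, config.adam_beta2, config.adam_eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: ModelParams, grads: ModelParams) -> None:
        self.t += 1
        for key, g in grads.items():
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            m_hat = self.m[key] / (1 - self.b1**self.t)
            v_hat = self.v[key] / (1 - self.b2**self.t)
            params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _evaluate(s, x, y, params, config, k) -> tuple[float, float]:
    probs, _ = forward_batch(s, x, params, config, k, train=False)
    loss = bce_loss(probs[:, 1], y, eps=config.loss_eps)
    acc = float((probs.argmax(axis=1) == y).mean())
    return loss, acc


def train_model(
    train_graphs: Sequence[BrainGraph],
    val_graphs: Sequence[BrainGraph] | None,
    config: DGCNNConfig,
) -> tuple[ModelParams, TrainingHistory]:
    """Train from scratch with shuffled mini-batches; reproducible via config.seed."""
    if len(train_graphs) == 0:
        raise ValueError("empty training set")
    labels = {g.label for g in train_graphs}
    if len(labels) < 2:
        raise ValueError(f"training set contains a single class: {labels}")

    s_tr, x_tr, y_tr = prepare_inputs(train_graphs)
    n = len(train_graphs)
    k = config.resolve_k(train_graphs[0].n_nodes)
    head_geometry(config, k)  # validate geometry up front
    if val_graphs:
        s_va, x_va, y_va = prepare_inputs(val_graphs)

    rng = np.random.default_rng(config.seed)
    params = init_params(x_tr.shape[2], config, rng, k)
    opt = _Adam(params, config)
    history = TrainingHistory()

    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            probs, cache = forward_batch(
                s_tr[idx], x_tr[idx], params, config, k, train=True, rng=rng
            )
            _, d_logits = bce_loss_grad_logits(probs, y_tr[idx], eps=config.loss_eps)
            grads = backward_batch(d_logits, cache, params, config)
            opt.step(params, grads)

        tr_loss, tr_acc = _evaluate(s_tr, x_tr, y_tr, params, config, k)
        history.train_loss.append(tr_loss)
        history.train_acc.append(tr_acc)
        if val_graphs:
            va_loss, va_acc = _evaluate(s_va, x_va, y_va, params, config, k)
            history.val_loss.append(va_loss)
            history.val_acc.append(va_acc)

    return params, history


class DGCNNClassifier:
    """scikit-learn-flavoured wrapper: fit on graphs, predict probabilities."""

    def __init__(self, config: DGCNNConfig) -> None:
        self.config = config
        self.params: ModelParams | None = None
        self.history: TrainingHistory | None = None

    def fit(
        self,
        graphs: Sequence[BrainGraph],
        val_graphs: Sequence[BrainGraph] | None = None,
    ) -> "DGCNNClassifier":
        self.params, self.history = train_model(graphs, val_graphs, self.config)
        return self

    def predict_proba(self, graphs: Sequence[BrainGraph]) -> np.ndarray:
        """Positive-class (MDD) probability per graph."""
        if self.params is None:
            raise RuntimeError("classifier is not fitted")
        from .model import predict

        return np.array([p.p_mdd for p in predict(self.params, self.config, graphs)])

    def predict(self, graphs: Sequence[BrainGraph]) -> list[str]:
        proba = self.predict_proba(graphs)
        from ..fc_network import NC

        return [MDD if p >= 0.5 else NC for p in proba]
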