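"""Architecture and training hyperparameters for the graph classifier."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field


@dataclass(frozen=True)
class DGCNNConfig:
    """Hyperparameters of the deep graph convolutional classifier.

    The default stack is four graph-conv layers with channel widths
    (32, 32, 32, 1) and tanh activations; all layer outputs are concatenated
    and sort-pooled to ``k`` rows (``k=None`` means "use the node count of
    the first graph seen"). The head is a 1-D conv whose kernel width and
    stride equal the total channel count, a (2, 2) max-pool, a width-5 1-D
    conv, a dense layer, dropout, and a 2-way softmax. Training uses BCE
    loss and Adam.
    """

    conv_channels: tuple[int, ...] = (32, 32, 32, 1)
    k: int | None = None
    conv1_filters: int = 16
    conv2_filters: int = 32
    conv2_width: int = 5
    pool_width: int = 2
    pool_stride: int = 2
    dense_width: int = 128
    dropout_rate: float = 0.5
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 50
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    loss_eps: float = 1e-7

    def __post_init__(self) -> None:
        object.__setattr__(self, "conv_channels", tuple(int(c) for c in self.conv_channels))
        if any(c < 1 for c in self.conv_channels) or not self.conv_channels:
            raise ValueError("conv_channels must be a nonempty tuple of positive integers")
        if self.k is not None and self.k < 1:
            raise ValueError("sort-pooling size k must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def total_channels(self) -> int:
        """Width of the concatenated graph-conv output fed to sort-pooling."""
        return sum(self.conv_channels)

    def resolve_k(self, n_nodes: int) -> int:
        return self.k if self.k is not None else int(n_nodes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_channels"] = list(self.conv_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DGCNNConfig":
        d = dict(d)
        if "conv_channels" in d:
            d["conv_channels"] = tuple(d["conv_channels"])
        return cls(**d)

    def replace(self, **kwargs) -> "DGCNNConfig":
        d = self.to_dict()
        d.update(kwargs)
        return DGCNNConfig.from_dict(d)
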