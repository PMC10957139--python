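"""Temporal convolutional network with gated residual blocks.

Stacked causal dilated 1-D convolutions; each block fuses a filter and a
gate path, z = tanh(W_f * x) ⊙ sigmoid(W_g * x), with an optional residual
skip (1x1 projection on channel mismatch). A global average pool over time
feeds a linear classification head.

The receptive field of a stack follows the dilated-causal recurrence
F_i = F_{i-1} + (k - 1) * l_i with F_0 = 1, which reduces to the vanilla
CNN span i*(k-1) + 1 when every dilation is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autograd import Tensor, causal_conv1d, softmax_cross_entropy

__all__ = ["TcnConfig", "tcn_receptive_field", "TcnClassifier"]

DILATION_CHOICES = (1, 2, 4, 8, 16, 32, 64, 128, 256)


@dataclass(frozen=True)
class TcnConfig:
    n_filters: int = 8
    kernel: int = 2
    dilations: tuple[int, ...] = (1, 2, 4)
    use_residual: bool = False

    def __post_init__(self) -> None:
        if not 2 <= self.n_filters <= 64:
            raise ValueError("n_filters must lie in [2, 64]")
        if not 2 <= self.kernel <= 16:
            raise ValueError("kernel must lie in [2, 16]")
        if not self.dilations:
            raise ValueError("need at least one layer dilation")
        if any(d not in DILATION_CHOICES for d in self.dilations):
            raise ValueError(f"dilations must come from {DILATION_CHOICES}")
        if list(self.dilations) != sorted(self.dilations):
            raise ValueError("dilations must be non-decreasing across layers")

    @property
    def n_layers(self) -> int:
        return len(self.dilations)


def tcn_receptive_field(k: int, dilations: Sequence[int]) -> int:
    """Span of past inputs influencing one output of the dilated stack."""
    if k < 2:
        raise ValueError("kernel must be at least 2")
    f = 1
    for l in dilations:
        f += (k - 1) * l
    return f


class TcnClassifier:
    model_id = "tcn"
    consumes = "raw"

    def __init__(
        self,
        input_dim: int,
        n_classes: int,
        config: TcnConfig = TcnConfig(),
        downsample: int = 1,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.n_classes = n_classes
        self.config = config
        self.downsample = int(downsample)
        self.quantized = False
        F, k = config.n_filters, config.kernel
        p: dict[str, Tensor] = {}
        cin = input_dim
        for i, dil in enumerate(config.dilations):
            scale = 1 / np.sqrt(cin * k)
            p[f"Wf{i}"] = Tensor.param(rng.uniform(-scale, scale, (F, cin, k)))
            p[f"bf{i}"] = Tensor.param(np.zeros(F))
            p[f"Wg{i}"] = Tensor.param(rng.uniform(-scale, scale, (F, cin, k)))
            p[f"bg{i}"] = Tensor.param(np.zeros(F))
            if config.use_residual and cin != F:
                p[f"Wr{i}"] = Tensor.param(rng.uniform(-scale, scale, (F, cin, 1)))
            cin = F
        p["Wo"] = Tensor.param(rng.uniform(-1 / np.sqrt(F), 1 / np.sqrt(F), (F, n_classes)))
        p["bo"] = Tensor.param(np.zeros(n_classes))
        self.p = p

    def params(self) -> dict[str, Tensor]:
        return self.p

    def features(self, X: np.ndarray) -> Tensor:
        """Pre-pooling activations, shape (B, F, T)."""
        X = X[:, :: self.downsample]
        h = Tensor(np.transpose(X, (0, 2, 1)))  # (B, C, T)
        for i, dil in enumerate(self.config.dilations):
            f = causal_conv1d(h, self.p[f"Wf{i}"], self.p[f"bf{i}"], dil)
            g = causal_conv1d(h, self.p[f"Wg{i}"], self.p[f"bg{i}"], dil)
            z = f.tanh() * g.sigmoid()
            if self.config.use_residual:
                skip = (
                    causal_conv1d(h, self.p[f"Wr{i}"], None, 1)
                    if f"Wr{i}" in self.p
                    else h
                )
                z = z + skip
            h = z
        return h

    def forward(self, X: np.ndarray) -> Tensor:
        pooled = self.features(X).mean(axis=2)
        return pooled @ self.p["Wo"] + self.p["bo"]

    def loss(self, X: np.ndarray, y: np.ndarray) -> Tensor:
        return softmax_cross_entropy(self.forward(X), y)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X).data.argmax(axis=1)

    # resource accounting ------------------------------------------------
    def weight_arrays(self) -> dict[str, np.ndarray]:
        return {k: t.data for k, t in self.p.items()}

    def activation_profile(self, input_shape) -> list[tuple[int, int]]:
        T = int(np.ceil(input_shape[0] / self.downsample))
        F = self.config.n_filters
        profile = []
        cin = self.input_dim
        for _ in self.config.dilations:
            profile.append((cin * T, F * T))
            cin = F
        profile.append((F, self.n_classes))  # pooled head
        return profile

    def flops(self, input_shape) -> int:
        T = int(np.ceil(input_shape[0] / self.downsample))
        F, k = self.config.n_filters, self.config.kernel
        total = 0
        cin = self.input_dim
        for _ in self.config.dilations:
            total += 2 * (2 * T * k * cin * F)  # filter + gate convolutions
            total += 3 * F * T  # tanh, sigmoid, gating product
            if self.config.use_residual:
                total += 2 * T * cin * F if cin != F else F * T
            cin = F
        total += F * T  # global average pool
        total += 2 * F * self.n_classes
        return total
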