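"""ProtoNN: prototype-based nearest-neighbour classifier in a learned
low-dimensional projection.

Scores are a kernel-weighted vote over m prototypes:
score(x) = sum_j Z_j * exp(-gamma^2 * ||W x - B_j||^2), with projection W,
prototype matrix B, per-prototype class scores Z, and kernel width gamma.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, softmax_cross_entropy

__all__ = ["ProtoNnParams", "protonn_predict", "ProtoNnClassifier"]


class ProtoNnParams:
    def __init__(self, W, B, Z, gamma):
        self.W = np.asarray(W, float)  # (p, d)
        self.B = np.asarray(B, float)  # (p, m)
        self.Z = np.asarray(Z, float)  # (C, m)
        self.gamma = float(gamma)
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.B.shape[0] != self.W.shape[0] or self.Z.shape[1] != self.B.shape[1]:
            raise ValueError("inconsistent ProtoNN parameter shapes")


def protonn_predict(x: np.ndarray, p: ProtoNnParams) -> np.ndarray:
    """Class scores for one sample or an (n, d) batch."""
    x = np.asarray(x, float)
    if x.ndim == 1:
        return protonn_predict(x[None, :], p)[0]
    proj = x @ p.W.T  # (n, p)
    d2 = ((proj[:, :, None] - p.B[None, :, :]) ** 2).sum(axis=1)  # (n, m)
    k = np.exp(-(p.gamma**2) * d2)
    return k @ p.Z.T


class ProtoNnClassifier:
    model_id = "protonn"
    consumes = "features"

    def __init__(
        self,
        input_dim: int,
        n_classes: int,
        projection_dim: int = 10,
        n_prototypes: int = 20,
        gamma: float = 0.05,
        seed: int = 0,
        init_X: np.ndarray | None = None,
        init_y: np.ndarray | None = None,
    ):
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.n_classes = n_classes
        self.projection_dim = projection_dim
        self.n_prototypes = n_prototypes
        self.gamma = float(gamma)
        self.quantized = False
        s = 1 / np.sqrt(input_dim)
        W = rng.uniform(-s, s, (projection_dim, input_dim))
        if init_X is not None and init_y is not None and len(init_X) >= n_prototypes:
            # seed prototypes from projected training samples, round-robin per class
            order = np.concatenate(
                [np.flatnonzero(init_y == c) for c in range(n_classes)]
            )
            picks = order[
                (np.arange(n_prototypes) * max(1, len(order) // n_prototypes))
                % len(order)
            ]
            B = (init_X[picks] @ W.T).T
            Z = np.zeros((n_classes, n_prototypes))
            Z[init_y[picks], np.arange(n_prototypes)] = 1.0
        else:
            B = rng.normal(0, 1.0, (projection_dim, n_prototypes))
            Z = rng.normal(0, 0.3, (n_classes, n_prototypes))
        self.p = {
            "W": Tensor.param(W),
            "B": Tensor.param(B),
            "Z": Tensor.param(Z),
        }
        self.in_mean = np.zeros(input_dim)
        self.in_scale = np.ones(input_dim)

    def set_standardizer(self, mean: np.ndarray, scale: np.ndarray) -> None:
        scale = np.where(scale > 0, scale, 1.0)
        self.in_mean = np.asarray(mean, float)
        self.in_scale = np.asarray(scale, float)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.in_mean) / self.in_scale

    def params(self) -> dict[str, Tensor]:
        return self.p

    def forward(self, X: np.ndarray) -> Tensor:
        Xt = Tensor(self._standardize(X))
        proj = Xt @ self.p["W"].transpose()  # (B, p)
        B = self.p["B"]
        # ||proj - B_j||^2 = ||proj||^2 + ||B_j||^2 - 2 proj.B_j
        p2 = (proj * proj).sum(axis=1, keepdims=True)
        b2 = (B * B).sum(axis=0, keepdims=True)
        cross = proj @ B
        d2 = p2 + b2 - 2.0 * cross
        k = (d2 * (-(self.gamma**2))).exp()
        return k @ self.p["Z"].transpose()

    def loss(self, X: np.ndarray, y: np.ndarray) -> Tensor:
        return softmax_cross_entropy(self.forward(X), y)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X).data.argmax(axis=1)

    def export_params(self) -> ProtoNnParams:
        return ProtoNnParams(
            W=self.p["W"].data, B=self.p["B"].data, Z=self.p["Z"].data, gamma=self.gamma
        )

    # resource accounting ------------------------------------------------
    def weight_arrays(self) -> dict[str, np.ndarray]:
        out = {k: t.data for k, t in self.p.items()}
        out["in_mean"] = self.in_mean
        out["in_scale"] = self.in_scale
        return out

    def activation_profile(self, input_shape) -> list[tuple[int, int]]:
        d, p, m = self.input_dim, self.projection_dim, self.n_prototypes
        return [(d, p), (p, m), (m, self.n_classes)]

    def flops(self, input_shape) -> int:
        d, p, m, c = self.input_dim, self.projection_dim, self.n_prototypes, self.n_classes
        return 2 * d * p + m * (3 * p + 1) + 2 * m * c
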