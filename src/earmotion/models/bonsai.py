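"""Bonsai: a shallow, sparse decision tree with non-linear node predictors
acting on a learned low-dimensional projection.

Every input is projected as x_hat = Z x. Each tree node k carries predictor
matrices (W_k, V_k) contributing W_k^T x_hat ⊙ tanh(sigma_b V_k^T x_hat) to
the class scores; internal nodes carry a branching vector T_k routing by
sign(T_k^T x_hat). Prediction accumulates contributions along the
root-to-leaf path. Training uses a soft path indicator (product of steep
sigmoids of the branching responses) so routing remains differentiable, and
a multiclass hinge loss; prediction uses hard sign routing.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["BonsaiParams", "bonsai_predict", "BonsaiClassifier"]


class BonsaiParams:
    """Plain-array container for the functional predictor."""

    def __init__(self, Z, W, V, T, sigma_b, depth):
        self.Z = np.asarray(Z, float)  # (p, d)
        self.W = np.asarray(W, float)  # (nodes, p, C)
        self.V = np.asarray(V, float)  # (nodes, p, C)
        self.T = np.asarray(T, float)  # (internal, p)
        self.sigma_b = float(sigma_b)
        self.depth = int(depth)
        n_nodes = 2**depth - 1
        if self.W.shape[0] != n_nodes or self.V.shape[0] != n_nodes:
            raise ValueError("W/V must carry one matrix per tree node")
        if depth > 1 and self.T.shape[0] != 2 ** (depth - 1) - 1:
            raise ValueError("T must carry one vector per internal node")


def _path_nodes(x_hat: np.ndarray, T: np.ndarray, depth: int) -> list[int]:
    """Root-to-leaf node indices for one projected sample, by branching sign."""
    path = [0]
    node = 0
    for _ in range(depth - 1):
        go_right = float(T[node] @ x_hat) >= 0
        node = 2 * node + (2 if go_right else 1)
        path.append(node)
    return path


def bonsai_predict(x: np.ndarray, p: BonsaiParams) -> np.ndarray:
    """Class scores for a single sample or an (n, d) batch (hard routing)."""
    x = np.asarray(x, float)
    if x.ndim == 1:
        return bonsai_predict(x[None, :], p)[0]
    if x.shape[1] != p.Z.shape[1]:
        raise ValueError("input dimension mismatch")
    x_hat = x @ p.Z.T
    scores = np.zeros((len(x), p.W.shape[2]))
    for i, xh in enumerate(x_hat):
        for k in _path_nodes(xh, p.T, p.depth):
            scores[i] += (p.W[k].T @ xh) * np.tanh(p.sigma_b * (p.V[k].T @ xh))
    return scores


class BonsaiClassifier:
    """Trainable Bonsai on feature vectors (soft routing during training)."""

    model_id = "bonsai"
    consumes = "features"

    def __init__(
        self,
        input_dim: int,
        n_classes: int,
        depth: int = 3,
        projection_dim: int = 10,
        sigma_b: float = 1.0,
        sigma_path: float = 4.0,
        seed: int = 0,
    ):
        if not 1 <= depth <= 6:
            raise ValueError("depth must lie in [1, 6]")
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.n_classes = n_classes
        self.depth = depth
        self.projection_dim = projection_dim
        self.sigma_b = sigma_b
        self.sigma_path = sigma_path  # steepness of the soft routing sigmoid
        self.quantized = False
        n_nodes = 2**depth - 1
        n_internal = 2 ** (depth - 1) - 1
        s = 1 / np.sqrt(input_dim)
        sp = 1 / np.sqrt(projection_dim)
        self.p = {
            "Z": Tensor.param(rng.uniform(-s, s, (projection_dim, input_dim))),
            "W": Tensor.param(rng.uniform(-sp, sp, (n_nodes, projection_dim, n_classes))),
            "V": Tensor.param(rng.uniform(-sp, sp, (n_nodes, projection_dim, n_classes))),
            "T": Tensor.param(rng.uniform(-sp, sp, (max(n_internal, 1), projection_dim))),
        }
        # input standardizer (fit on training data; stored with the model)
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

    def forward(self, X: np.ndarray, soft: bool = True) -> Tensor:
        """Class scores; soft=True uses differentiable path indicators."""
        X = self._standardize(X)
        Xt = Tensor(X)
        x_hat = Xt @ self.p["Z"].transpose()  # (B, p)
        n_nodes = 2**self.depth - 1
        # per-node indicator tensors (B, 1)
        ones = Tensor(np.ones((X.shape[0], 1)))
        indicators: list[Tensor | None] = [None] * n_nodes
        indicators[0] = ones
        if self.depth > 1:
            theta = self.sigma_path * (x_hat @ self.p["T"].transpose())  # (B, internal)
            for node in range(2 ** (self.depth - 1) - 1):
                right = theta[:, node : node + 1].sigmoid()
                left = 1.0 - right
                indicators[2 * node + 1] = indicators[node] * left
                indicators[2 * node + 2] = indicators[node] * right
        if not soft:
            hard = self._hard_indicators(np.asarray(X, float))
            indicators = [Tensor(hard[:, k : k + 1]) for k in range(n_nodes)]
        scores: Tensor | None = None
        for k in range(n_nodes):
            wk = x_hat @ self.p["W"][k]  # (B, C)
            vk = (x_hat @ self.p["V"][k]) * self.sigma_b
            contrib = indicators[k] * (wk * vk.tanh())
            scores = contrib if scores is None else scores + contrib
        return scores

    def _hard_indicators(self, X: np.ndarray) -> np.ndarray:
        n_nodes = 2**self.depth - 1
        x_hat = X @ self.p["Z"].data.T
        out = np.zeros((len(X), n_nodes))
        for i, xh in enumerate(x_hat):
            for k in _path_nodes(xh, self.p["T"].data, self.depth):
                out[i, k] = 1.0
        return out

    def loss(self, X: np.ndarray, y: np.ndarray) -> Tensor:
        from .training import multiclass_hinge_loss

        return multiclass_hinge_loss(self.forward(X, soft=True), y)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, soft=False).data.argmax(axis=1)

    def export_params(self) -> BonsaiParams:
        return BonsaiParams(
            Z=self.p["Z"].data,
            W=self.p["W"].data,
            V=self.p["V"].data,
            T=self.p["T"].data,
            sigma_b=self.sigma_b,
            depth=self.depth,
        )

    # resource accounting ------------------------------------------------
    def weight_arrays(self) -> dict[str, np.ndarray]:
        out = {k: t.data for k, t in self.p.items()}
        out["in_mean"] = self.in_mean
        out["in_scale"] = self.in_scale
        return out

    def activation_profile(self, input_shape) -> list[tuple[int, int]]:
        d, p = self.input_dim, self.projection_dim
        return [(d, p), (p, self.n_classes)]

    def flops(self, input_shape) -> int:
        d, p, c = self.input_dim, self.projection_dim, self.n_classes
        per_node = 2 * (2 * p * c) + 2 * c  # W and V products, gating
        return 2 * d * p + self.depth * per_node + (self.depth - 1) * 2 * p
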