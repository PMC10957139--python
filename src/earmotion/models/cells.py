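"""FastRNN and FastGRNN: stabilized lightweight recurrent classifiers.

FastRNN damps the exploding/vanishing-gradient problem of a vanilla RNN with
a weighted residual connection h_t = alpha * h~_t + beta * h_{t-1}, with
0 <= alpha << 1 and beta ~ 1 - alpha at initialization. FastGRNN turns that
residual pair into a gate z_t sharing the pre-activation of the candidate
state, optionally with low-rank factored matrices W' = W1 W2^T, U' = U1 U2^T.

Functional single-step forms (`fastrnn_step`, `fastgrnn_step`) operate on
plain arrays; the classifier classes mirror them on the autodiff engine and
add a linear read-out over the final hidden state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, softmax_cross_entropy

__all__ = [
    "FastRnnParams",
    "FastGrnnParams",
    "fastrnn_step",
    "fastgrnn_step",
    "FastRnnClassifier",
    "FastGrnnClassifier",
]


@dataclass
class FastRnnParams:
    W: np.ndarray  # (h, d)
    U: np.ndarray  # (h, h)
    b: np.ndarray  # (h,)
    alpha: float
    beta_res: float

    def __post_init__(self) -> None:
        h, d = np.shape(self.W)
        if np.shape(self.U) != (h, h) or np.shape(self.b) != (h,):
            raise ValueError("inconsistent FastRNN parameter shapes")


def fastrnn_step(h: np.ndarray, x: np.ndarray, p: FastRnnParams) -> np.ndarray:
    """h' = alpha * tanh(W x + U h + b) + beta_res * h."""
    h = np.asarray(h, float)
    x = np.asarray(x, float)
    if x.shape[-1] != p.W.shape[1] or h.shape[-1] != p.U.shape[1]:
        raise ValueError("dimension mismatch in fastrnn_step")
    h_tilde = np.tanh(x @ p.W.T + h @ p.U.T + p.b)
    return p.alpha * h_tilde + p.beta_res * h


@dataclass
class FastGrnnParams:
    """Low-rank gate parameters; W2/U2 = None means full rank (W' = W1)."""

    W1: np.ndarray
    U1: np.ndarray
    b_h: np.ndarray
    b_z: np.ndarray
    zeta: float
    nu: float
    W2: np.ndarray | None = None
    U2: np.ndarray | None = None

    @property
    def W(self) -> np.ndarray:
        return self.W1 if self.W2 is None else self.W1 @ self.W2.T

    @property
    def U(self) -> np.ndarray:
        return self.U1 if self.U2 is None else self.U1 @ self.U2.T


def fastgrnn_step(h: np.ndarray, x: np.ndarray, p: FastGrnnParams) -> np.ndarray:
    """Gated update sharing one pre-activation between candidate and gate.

    z  = sigmoid(W' x + U' h + b_z)
    h~ = tanh   (W' x + U' h + b_h)
    h' = (zeta * (1 - z) + nu) * h~ + z * h
    """
    h = np.asarray(h, float)
    x = np.asarray(x, float)
    W, U = p.W, p.U
    if x.shape[-1] != W.shape[1] or h.shape[-1] != U.shape[1]:
        raise ValueError("dimension mismatch in fastgrnn_step")
    pre = x @ W.T + h @ U.T
    z = 1.0 / (1.0 + np.exp(-(pre + p.b_z)))
    h_tilde = np.tanh(pre + p.b_h)
    return (p.zeta * (1.0 - z) + p.nu) * h_tilde + z * h


def _uniform(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape)


class FastRnnClassifier:
    """FastRNN over raw (B, T, C) windows with a linear head on h_T."""

    model_id = "fastrnn"
    consumes = "raw"

    def __init__(
        self,
        input_dim: int,
        hidden_dim: int,
        n_classes: int,
        alpha_init: float = 0.05,
        beta_init: float = 0.95,
        downsample: int = 1,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        self.n_classes = n_classes
        self.downsample = int(downsample)
        self.quantized = False
        self.p = {
            "W": Tensor.param(_uniform(rng, (input_dim, hidden_dim), 1 / np.sqrt(input_dim))),
            "U": Tensor.param(_uniform(rng, (hidden_dim, hidden_dim), 1 / np.sqrt(hidden_dim))),
            "b": Tensor.param(np.zeros(hidden_dim)),
            "alpha": Tensor.param(np.array(alpha_init)),
            "beta": Tensor.param(np.array(beta_init)),
            "Wo": Tensor.param(_uniform(rng, (hidden_dim, n_classes), 1 / np.sqrt(hidden_dim))),
            "bo": Tensor.param(np.zeros(n_classes)),
        }

    def params(self) -> dict[str, Tensor]:
        return self.p

    def forward(self, X: np.ndarray) -> Tensor:
        X = X[:, :: self.downsample]
        B, T, d = X.shape
        xw_all = Tensor(X.reshape(B * T, d)) @ self.p["W"]
        h = Tensor(np.zeros((B, self.hidden_dim)))
        idx0 = np.arange(B) * T
        for t in range(T):
            pre = xw_all[idx0 + t] + h @ self.p["U"] + self.p["b"]
            h = self.p["alpha"] * pre.tanh() + self.p["beta"] * h
        return h @ self.p["Wo"] + self.p["bo"]

    def loss(self, X: np.ndarray, y: np.ndarray) -> Tensor:
        return softmax_cross_entropy(self.forward(X), y)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X).data.argmax(axis=1)

    # resource accounting ------------------------------------------------
    def weight_arrays(self) -> dict[str, np.ndarray]:
        return {k: t.data for k, t in self.p.items()}

    def activation_profile(self, input_shape) -> list[tuple[int, int]]:
        # streaming inference holds (x_t, h) then (h, logits)
        return [
            (self.input_dim, self.hidden_dim),
            (self.hidden_dim, self.n_classes),
        ]

    def flops(self, input_shape) -> int:
        T = int(np.ceil(input_shape[0] / self.downsample))
        d, h, c = self.input_dim, self.hidden_dim, self.n_classes
        per_step = 2 * d * h + 2 * h * h + 5 * h  # MACs*2 + tanh/residual
        return T * per_step + 2 * h * c


class FastGrnnClassifier:
    """FastGRNN over raw (B, T, C) windows; optional low-rank factors."""

    model_id = "fastgrnn"
    consumes = "raw"

    def __init__(
        self,
        input_dim: int,
        hidden_dim: int,
        n_classes: int,
        rank: int | None = None,
        zeta_init: float = 1.0,
        nu_init: float = 0.0,
        downsample: int = 1,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        self.n_classes = n_classes
        self.rank = rank
        self.downsample = int(downsample)
        self.quantized = False
        p: dict[str, Tensor] = {}
        if rank is None:
            p["W1"] = Tensor.param(_uniform(rng, (input_dim, hidden_dim), 1 / np.sqrt(input_dim)))
            p["U1"] = Tensor.param(_uniform(rng, (hidden_dim, hidden_dim), 1 / np.sqrt(hidden_dim)))
        else:
            p["W1"] = Tensor.param(_uniform(rng, (input_dim, rank), 1 / np.sqrt(input_dim)))
            p["W2"] = Tensor.param(_uniform(rng, (rank, hidden_dim), 1 / np.sqrt(rank)))
            p["U1"] = Tensor.param(_uniform(rng, (hidden_dim, rank), 1 / np.sqrt(hidden_dim)))
            p["U2"] = Tensor.param(_uniform(rng, (rank, hidden_dim), 1 / np.sqrt(rank)))
        p["b_h"] = Tensor.param(np.zeros(hidden_dim))
        p["b_z"] = Tensor.param(np.ones(hidden_dim))  # gate starts mostly open
        p["zeta"] = Tensor.param(np.array(zeta_init))
        p["nu"] = Tensor.param(np.array(nu_init))
        p["Wo"] = Tensor.param(_uniform(rng, (hidden_dim, n_classes), 1 / np.sqrt(hidden_dim)))
        p["bo"] = Tensor.param(np.zeros(n_classes))
        self.p = p

    def params(self) -> dict[str, Tensor]:
        return self.p

    def forward(self, X: np.ndarray) -> Tensor:
        X = X[:, :: self.downsample]
        B, T, d = X.shape
        xt = Tensor(X.reshape(B * T, d))
        if self.rank is None:
            xw_all = xt @ self.p["W1"]
        else:
            xw_all = (xt @ self.p["W1"]) @ self.p["W2"]
        h = Tensor(np.zeros((B, self.hidden_dim)))
        idx0 = np.arange(B) * T
        for t in range(T):
            if self.rank is None:
                uh = h @ self.p["U1"]
            else:
                uh = (h @ self.p["U1"]) @ self.p["U2"]
            pre = xw_all[idx0 + t] + uh
            z = (pre + self.p["b_z"]).sigmoid()
            h_tilde = (pre + self.p["b_h"]).tanh()
            gate = self.p["zeta"] * (1.0 - z) + self.p["nu"]
            h = gate * h_tilde + z * h
        return h @ self.p["Wo"] + self.p["bo"]

    def loss(self, X: np.ndarray, y: np.ndarray) -> Tensor:
        return softmax_cross_entropy(self.forward(X), y)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X).data.argmax(axis=1)

    def weight_arrays(self) -> dict[str, np.ndarray]:
        return {k: t.data for k, t in self.p.items()}

    def activation_profile(self, input_shape) -> list[tuple[int, int]]:
        return [
            (self.input_dim, self.hidden_dim),
            (self.hidden_dim, self.n_classes),
        ]

    def flops(self, input_shape) -> int:
        T = int(np.ceil(input_shape[0] / self.downsample))
        d, h, c = self.input_dim, self.hidden_dim, self.n_classes
        if self.rank is None:
            mac = d * h + h * h
        else:
            r = self.rank
            mac = r * (d + h) + r * (h + h)
        per_step = 2 * mac + 9 * h  # shared pre-activation, two nonlinearities
        return T * per_step + 2 * h * c
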