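"""Gradient training for the lightweight classifiers.

All models minimize cross-entropy except Bonsai, which uses a multiclass
(Crammer-Singer) hinge loss. Sparsity is enforced by iterative hard
thresholding (IHT): after a dense warm phase, each listed parameter matrix
is projected onto its top-|s| magnitudes after every optimizer step.
Training is deterministic given (seed, config).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Tensor
from .bonsai import BonsaiClassifier
from .cells import FastGrnnClassifier, FastRnnClassifier
from .protonn import ProtoNnClassifier
from .tcn import TcnClassifier, TcnConfig

__all__ = [
    "MODEL_IDS",
    "TrainingFailure",
    "multiclass_hinge_loss",
    "iht_project",
    "build_model",
    "train_model",
    "TrainedModel",
]

MODEL_IDS = ("fastrnn", "fastgrnn", "tcn", "bonsai", "protonn")

# learning rates and sparsity fractions (nonzero density per matrix)
_DEFAULT_LR = {"tcn": 0.001, "fastgrnn": 0.01, "fastrnn": 0.01, "bonsai": 0.01, "protonn": 0.03}
_DEFAULT_SPARSITY: dict[str, dict[str, float]] = {
    "bonsai": {"Z": 0.2, "W": 0.3, "V": 0.3, "T": 0.62},
    "protonn": {"W": 0.8},
}
# L2 regularization per matrix (max-margin behaviour under the hinge loss)
_DEFAULT_REG: dict[str, dict[str, float]] = {
    "bonsai": {"Z": 1e-4, "W": 1e-3, "V": 1e-3, "T": 1e-3},
    "protonn": {"W": 5e-6, "B": 0.0, "Z": 5e-5},
}
_DECAY_STEP, _DECAY_RATE = 200, 0.1  # stepwise lr decay for the recurrent cells


class TrainingFailure(RuntimeError):
    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


def multiclass_hinge_loss(scores: Tensor, y: np.ndarray) -> Tensor:
    """Crammer-Singer hinge: mean relu(1 + max_{c != y} s_c - s_y)."""
    s = scores.data
    n = len(y)
    masked = s.copy()
    masked[np.arange(n), y] = -np.inf
    viol = masked.argmax(axis=1)
    rows = np.arange(n)
    margin = 1.0 + scores[rows, viol] - scores[rows, y]
    return margin.relu().mean()


def iht_project(arr: np.ndarray, density: float) -> np.ndarray:
    """Keep the top density*size magnitudes of ``arr``, zero the rest."""
    if density >= 1.0:
        return arr
    keep = max(1, int(round(density * arr.size)))
    flat = np.abs(arr).ravel()
    if keep >= arr.size:
        return arr
    thresh = np.partition(flat, -keep)[-keep]
    out = np.where(np.abs(arr) >= thresh, arr, 0.0)
    return out


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


def build_model(model_id: str, input_shape, n_classes: int, config: dict, seed: int):
    """Instantiate a classifier from its id and hyperparameter dict.

    ``input_shape`` is (T, channels) for raw-input models and (dim,) for
    feature-input models.
    """
    cfg = dict(config or {})
    if model_id == "fastrnn":
        return FastRnnClassifier(
            input_dim=input_shape[1],
            hidden_dim=cfg.get("hidden_dim", 32),
            n_classes=n_classes,
            alpha_init=cfg.get("alpha_init", 0.05),
            beta_init=cfg.get("beta_init", 0.95),
            downsample=cfg.get("downsample", 1),
            seed=seed,
        )
    if model_id == "fastgrnn":
        return FastGrnnClassifier(
            input_dim=input_shape[1],
            hidden_dim=cfg.get("hidden_dim", 32),
            n_classes=n_classes,
            rank=cfg.get("rank"),
            downsample=cfg.get("downsample", 1),
            seed=seed,
        )
    if model_id == "tcn":
        tcn_cfg = cfg.get("tcn_config") or TcnConfig(
            n_filters=cfg.get("n_filters", 8),
            kernel=cfg.get("kernel", 2),
            dilations=tuple(cfg.get("dilations", (1, 2, 4))),
            use_residual=cfg.get("use_residual", False),
        )
        return TcnClassifier(
            input_dim=input_shape[1],
            n_classes=n_classes,
            config=tcn_cfg,
            downsample=cfg.get("downsample", 1),
            seed=seed,
        )
    if model_id == "bonsai":
        return BonsaiClassifier(
            input_dim=input_shape[0],
            n_classes=n_classes,
            depth=cfg.get("depth", 3),
            projection_dim=cfg.get("projection_dim", 10),
            sigma_b=cfg.get("sigma_b", 1.0),
            seed=seed,
        )
    if model_id == "protonn":
        return ProtoNnClassifier(
            input_dim=input_shape[0],
            n_classes=n_classes,
            projection_dim=cfg.get("projection_dim", 10),
            n_prototypes=cfg.get("n_prototypes", 20),
            gamma=cfg.get("gamma", 0.05),
            seed=seed,
            init_X=cfg.get("_init_X"),
            init_y=cfg.get("_init_y"),
        )
    raise ValueError(f"unknown model id {model_id!r}")


@dataclass
class TrainedModel:
    model_id: str
    model: object
    history: list[dict]
    config: dict
    seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == y))

    def save(self, path: str | Path) -> None:
        """Versioned JSON checkpoint (weights as nested lists)."""
        payload = {
            "format_version": 1,
            "model_id": self.model_id,
            "config": {k: v for k, v in self.config.items() if not k.startswith("_")},
            "seed": self.seed,
            "weights": {k: v.tolist() for k, v in self.model.weight_arrays().items()},
        }
        Path(path).write_text(json.dumps(payload))


def train_model(
    model_id: str,
    dataset: dict,
    config: dict | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Train one classifier on a prepared dataset.

    ``dataset`` carries ``X`` ((n, T, C) raw windows or (n, d) features) and
    integer ``y``; optional ``X_val``/``y_val`` are scored per epoch.
    ``config`` keys: epochs, batch_size, lr, sparsity (dict name->density),
    warm_fraction, plus model hyperparameters (see ``build_model``).
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}")
    cfg = dict(config or {})
    X = np.asarray(dataset["X"], float)
    y = np.asarray(dataset["y"], int)
    n_classes = int(cfg.get("n_classes", y.max() + 1))
    epochs = int(cfg.get("epochs", 20))
    batch_size = int(cfg.get("batch_size", 128))
    lr = float(cfg.get("lr", _DEFAULT_LR[model_id]))
    sparsity = cfg.get("sparsity", _DEFAULT_SPARSITY.get(model_id, {}))
    reg = cfg.get("regularization", _DEFAULT_REG.get(model_id, {}))
    warm_fraction = float(cfg.get("warm_fraction", 0.5))

    standardizer = None
    if model_id in ("bonsai", "protonn"):
        mu = X.mean(axis=0)
        sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        standardizer = (mu, sd)
    if model_id == "protonn":
        cfg["_init_X"], cfg["_init_y"] = (X - mu) / sd, y
    input_shape = X.shape[1:] if X.ndim == 3 else (X.shape[1],)
    model = build_model(model_id, input_shape, n_classes, cfg, seed)
    if standardizer is not None:
        model.set_standardizer(*standardizer)
    opt = Adam(model.params(), lr)
    rng = np.random.default_rng(seed + 1)
    history: list[dict] = []
    warm_epochs = int(np.ceil(warm_fraction * epochs))

    step = 0
    for epoch in range(epochs):
        order = rng.permutation(len(X))
        losses = []
        for lo in range(0, len(X), batch_size):
            idx = order[lo : lo + batch_size]
            opt.zero_grad()
            loss = model.loss(X[idx], y[idx])
            if not np.isfinite(loss.data):
                raise TrainingFailure(
                    "non-finite training loss",
                    {"model_id": model_id, "epoch": epoch, "step": step},
                )
            loss.backward()
            for name, lam in reg.items():
                if lam and name in model.params():
                    p = model.params()[name]
                    p._accumulate(lam * p.data)
            opt.step()
            step += 1
            if model_id in ("fastrnn", "fastgrnn") and step % _DECAY_STEP == 0:
                opt.lr *= _DECAY_RATE
            if sparsity and epoch >= warm_epochs:
                for name, density in sparsity.items():
                    if name in model.params():
                        p = model.params()[name]
                        p.data = iht_project(p.data, density)
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        if "X_val" in dataset and dataset["X_val"] is not None and len(dataset["X_val"]):
            entry["val_accuracy"] = float(
                np.mean(model.predict(np.asarray(dataset["X_val"])) == dataset["y_val"])
            )
        history.append(entry)
    # a final projection guarantees the advertised sparsity on exit
    if sparsity:
        for name, density in sparsity.items():
            if name in model.params():
                p = model.params()[name]
                p.data = iht_project(p.data, density)
    return TrainedModel(model_id=model_id, model=model, history=history, config=cfg, seed=seed)
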