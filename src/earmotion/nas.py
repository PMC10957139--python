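"""Hardware-aware multi-objective Bayesian architecture search.

The search treats model design as black-box minimization of a random
scalarization of four objectives — validation error, flash utilization,
SRAM utilization (both negative within budget, +inf beyond it), and a
latency proxy — over a structured space of architectures. A Gaussian
process (Matern-5/2, ARD) surrogate is fit on the negated composite and an
upper-confidence-bound acquisition mu + sqrt(beta) * sigma is maximized
over a Monte-Carlo candidate pool, so only valid configurations are ever
scored. Batch suggestion supports a constant-liar ("hallucination")
strategy and a k-means diversification strategy.

Resource figures come from analytic proxies or from a (mock)
hardware-in-the-loop backend; when the backend is unavailable the search
falls back to proxies for that evaluation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

from .resources import (
    DeviceSpec,
    HilUnavailable,
    ResourceReport,
    feasibility,
    hil_measure,
    proxy_report,
)

__all__ = [
    "IntDim",
    "ChoiceDim",
    "BoolDim",
    "SearchSpace",
    "tcn_search_space",
    "ObjectiveVector",
    "encode_config",
    "decode_vector",
    "sample_candidates",
    "Surrogate",
    "ucb_select",
    "batch_suggest",
    "evaluate_config",
    "nas_search",
    "NasResult",
    "LambdaDomain",
]


# ------------------------------------------------------------ search space


@dataclass(frozen=True)
class IntDim:
    name: str
    lo: int
    hi: int

    def encode(self, v) -> list[float]:
        return [(int(v) - self.lo) / (self.hi - self.lo)]

    def decode(self, vals: Sequence[float]) -> int:
        return int(round(vals[0] * (self.hi - self.lo) + self.lo))

    @property
    def width(self) -> int:
        return 1

    def sample(self, rng):
        return int(rng.integers(self.lo, self.hi + 1))


@dataclass(frozen=True)
class ChoiceDim:
    name: str
    choices: tuple

    def encode(self, v) -> list[float]:
        out = [0.0] * len(self.choices)
        out[self.choices.index(v)] = 1.0
        return out

    def decode(self, vals: Sequence[float]) -> object:
        return self.choices[int(np.argmax(vals))]

    @property
    def width(self) -> int:
        return len(self.choices)

    def sample(self, rng):
        return self.choices[int(rng.integers(len(self.choices)))]


@dataclass(frozen=True)
class BoolDim:
    name: str

    def encode(self, v) -> list[float]:
        return [1.0 if v else 0.0]

    def decode(self, vals: Sequence[float]) -> bool:
        return vals[0] >= 0.5

    @property
    def width(self) -> int:
        return 1

    def sample(self, rng):
        return bool(rng.integers(2))


@dataclass
class SearchSpace:
    """Named dimensions plus optional validity/canonicalization hooks."""

    dims: list
    validator: Callable[[dict], bool] | None = None
    canonicalizer: Callable[[dict], dict] | None = None
    sampler: Callable[[np.random.Generator], dict] | None = None

    def is_valid(self, cfg: dict) -> bool:
        if set(cfg) != {d.name for d in self.dims}:
            return False
        for d in self.dims:
            try:
                d.encode(cfg[d.name])
            except (ValueError, KeyError):
                return False
            if isinstance(d, IntDim) and not d.lo <= cfg[d.name] <= d.hi:
                return False
        return self.validator(cfg) if self.validator else True

    def canonicalize(self, cfg: dict) -> dict:
        return self.canonicalizer(cfg) if self.canonicalizer else dict(cfg)

    def sample(self, rng: np.random.Generator) -> dict:
        if self.sampler is not None:
            return self.canonicalize(self.sampler(rng))
        for _ in range(1000):  # rejection sampling over per-dim draws
            cfg = self.canonicalize({d.name: d.sample(rng) for d in self.dims})
            if self.is_valid(cfg):
                return cfg
        raise RuntimeError("could not sample a valid configuration")

    def enumerate(self, limit: int = 100_000) -> list[dict] | None:
        """All valid configs, or None when the space is too large."""
        sizes = []
        for d in self.dims:
            if isinstance(d, IntDim):
                sizes.append(d.hi - d.lo + 1)
            elif isinstance(d, ChoiceDim):
                sizes.append(len(d.choices))
            else:
                sizes.append(2)
        if np.prod(sizes, dtype=float) > limit:
            return None
        values = []
        for d in self.dims:
            if isinstance(d, IntDim):
                values.append(list(range(d.lo, d.hi + 1)))
            elif isinstance(d, ChoiceDim):
                values.append(list(d.choices))
            else:
                values.append([False, True])
        out, seen = [], set()
        for combo in itertools.product(*values):
            cfg = self.canonicalize(dict(zip((d.name for d in self.dims), combo)))
            key = config_key(cfg)
            if key not in seen and self.is_valid(cfg):
                seen.add(key)
                out.append(cfg)
        return out


def config_key(cfg: dict) -> str:
    return json.dumps({k: cfg[k] for k in sorted(cfg)}, sort_keys=True, default=str)


def tcn_search_space(max_layers: int = 8) -> SearchSpace:
    """The TCN design space: filters 2-64, kernel 2-16, 3-8 layers with
    non-decreasing dilations from {1..256}, optional residual skips."""
    dil_choices = (1, 2, 4, 8, 16, 32, 64, 128, 256)
    dims = [
        IntDim("n_filters", 2, 64),
        IntDim("kernel", 2, 16),
        IntDim("n_layers", 3, max_layers),
        BoolDim("use_residual"),
    ] + [ChoiceDim(f"dilation_{i}", dil_choices) for i in range(max_layers)]

    def canonicalize(cfg: dict) -> dict:
        out = dict(cfg)
        n = out["n_layers"]
        used = sorted(out[f"dilation_{i}"] for i in range(n))
        for i in range(max_layers):
            out[f"dilation_{i}"] = used[i] if i < n else 1
        return out

    def valid(cfg: dict) -> bool:
        n = cfg["n_layers"]
        used = [cfg[f"dilation_{i}"] for i in range(n)]
        if used != sorted(used):
            return False
        return all(cfg[f"dilation_{i}"] == 1 for i in range(n, max_layers))

    return SearchSpace(dims=dims, validator=valid, canonicalizer=canonicalize)


def encode_config(cfg: dict, space: SearchSpace) -> np.ndarray:
    """Map a valid config to a fixed-length real vector: ordinal dims scale
    to [0, 1], categorical dims one-hot."""
    if not space.is_valid(cfg):
        raise ValueError("configuration is not a member of the search space")
    vec: list[float] = []
    for d in space.dims:
        vec.extend(d.encode(cfg[d.name]))
    return np.asarray(vec)


def decode_vector(vec: np.ndarray, space: SearchSpace) -> dict:
    cfg = {}
    i = 0
    for d in space.dims:
        cfg[d.name] = d.decode(vec[i : i + d.width])
        i += d.width
    return space.canonicalize(cfg)


def sample_candidates(space: SearchSpace, n: int, seed: int) -> list[dict]:
    """Draw n valid configurations uniformly (seed-deterministic)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    return [space.sample(rng) for _ in range(n)]


# ------------------------------------------------------------- objectives


@dataclass(frozen=True)
class ObjectiveVector:
    f_error: float
    f_flash: float
    f_sram: float
    f_latency: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f_error, self.f_flash, self.f_sram, self.f_latency])

    @property
    def feasible(self) -> bool:
        return bool(np.all(np.isfinite(self.as_array())))

    def composite(self, lam: Sequence[float]) -> float:
        return float(np.dot(np.asarray(lam), self.as_array()))


def dominates(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    """a dominates b: no worse in all four objectives, strictly better in one."""
    av, bv = a.as_array(), b.as_array()
    return bool(np.all(av <= bv) and np.any(av < bv))


@dataclass(frozen=True)
class LambdaDomain:
    """Developer-specified domain of random scalarization weights.

    The default draws positive weights uniformly from the 4-simplex; the
    reference weight (used for incumbent tracking) is its mean.
    """

    alpha: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.dirichlet(self.alpha)

    def reference(self) -> np.ndarray:
        a = np.asarray(self.alpha)
        return a / a.sum()


# -------------------------------------------------------------- surrogate


class Surrogate:
    """GP over encoded configs, fit on the negated composite (so that UCB
    maximization seeks the minimum of f_opt)."""

    def __init__(self, space: SearchSpace, seed: int = 0):
        self.space = space
        self.X: list[np.ndarray] = []
        self.y: list[float] = []  # composite f_opt values (to be minimized)
        self._gp: GaussianProcessRegressor | None = None
        self.seed = seed

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def add(self, cfg: dict, f_opt: float) -> None:
        self.X.append(encode_config(cfg, self.space))
        self.y.append(float(f_opt))
        self._gp = None

    def set_observations(self, cfgs: Sequence[dict], f_opts: Sequence[float]) -> None:
        self.X = [encode_config(c, self.space) for c in cfgs]
        self.y = [float(v) for v in f_opts]
        self._gp = None

    def _finite_targets(self) -> np.ndarray:
        """Budget violations carry +inf composites; cap them at a finite
        penalty so the GP stays well-posed while still repelling the search."""
        y = np.asarray(self.y)
        finite = y[np.isfinite(y)]
        if len(finite) == 0:
            return np.zeros_like(y)
        cap = finite.max() + 3.0 * max(np.ptp(finite), 1.0)
        return np.where(np.isfinite(y), y, cap)

    def fit(self) -> None:
        if not self.X:
            raise ValueError("cannot fit surrogate with no observations")
        dim = len(self.X[0])
        kernel = ConstantKernel(1.0) * Matern(length_scale=np.ones(dim), nu=2.5)
        self._gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=1e-6,
            normalize_y=True,
            n_restarts_optimizer=0,
            random_state=self.seed,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._gp.fit(np.stack(self.X), -self._finite_targets())

    def predict(self, cfgs: Sequence[dict]) -> tuple[np.ndarray, np.ndarray]:
        """Posterior (mu, sigma) of the negated composite at given configs."""
        if self._gp is None:
            self.fit()
        Xc = np.stack([encode_config(c, self.space) for c in cfgs])
        mu, sigma = self._gp.predict(Xc, return_std=True)
        return mu, sigma


def ucb_select(
    surrogate: Surrogate, candidates: Sequence[dict], beta_ucb: float = 4.0
) -> dict:
    """argmax over candidates of mu + sqrt(beta) * sigma; ties break toward
    the lowest candidate index. With no observations, the first candidate
    is returned (uniform pool makes this a uniform pick)."""
    if not candidates:
        raise ValueError("empty candidate pool")
    if surrogate.n_obs == 0:
        return candidates[0]
    mu, sigma = surrogate.predict(candidates)
    acq = mu + np.sqrt(beta_ucb) * sigma
    return candidates[int(np.argmax(acq))]


def batch_suggest(
    surrogate: Surrogate,
    candidates: Sequence[dict],
    batch_size: int,
    strategy: str = "hallucination",
    beta_ucb: float = 4.0,
    seed: int = 0,
) -> list[dict]:
    """Pick a batch of distinct configs for parallel evaluation.

    ``hallucination`` is the constant-liar scheme: after each pick the
    surrogate temporarily absorbs the posterior mean at the pick before
    re-selecting. ``kmeans`` clusters the top-acquisition candidates in
    encoded space and returns the best-acquisition member of each cluster.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be at least 1")
    uniq: dict[str, dict] = {}
    for c in candidates:
        uniq.setdefault(config_key(c), c)
    pool = list(uniq.values())
    if batch_size > len(pool):
        raise ValueError("batch_size exceeds distinct candidate count")
    if surrogate.n_obs == 0:
        return pool[:batch_size]
    if strategy == "hallucination":
        lier = Surrogate(surrogate.space, seed=surrogate.seed)
        lier.set_observations(
            [decode_vector(x, surrogate.space) for x in surrogate.X], surrogate.y
        )
        picks: list[dict] = []
        remaining = list(pool)
        for _ in range(batch_size):
            choice = ucb_select(lier, remaining, beta_ucb)
            picks.append(choice)
            remaining = [c for c in remaining if config_key(c) != config_key(choice)]
            mu, _ = lier.predict([choice])
            lier.add(choice, -float(mu[0]))  # lie with the posterior mean
        return picks
    if strategy == "kmeans":
        mu, sigma = surrogate.predict(pool)
        acq = mu + np.sqrt(beta_ucb) * sigma
        top_n = min(len(pool), max(4 * batch_size, batch_size))
        top_idx = np.argsort(acq)[::-1][:top_n]
        X = np.stack([encode_config(pool[i], surrogate.space) for i in top_idx])
        km = KMeans(n_clusters=batch_size, n_init=4, random_state=seed).fit(X)
        picks = []
        for cluster in range(batch_size):
            members = top_idx[km.labels_ == cluster]
            if len(members) == 0:
                continue
            best = members[np.argmax(acq[members])]
            picks.append(pool[int(best)])
        # backfill if a cluster came out empty
        for i in np.argsort(acq)[::-1]:
            if len(picks) == batch_size:
                break
            if all(config_key(pool[int(i)]) != config_key(p) for p in picks):
                picks.append(pool[int(i)])
        return picks
    raise ValueError(f"unknown batch strategy {strategy!r}")


# -------------------------------------------------------------- evaluation


def evaluate_config(
    cfg: dict,
    dataset: dict,
    device: DeviceSpec,
    resource_source: str = "proxy",
    train_budget: dict | None = None,
    seed: int = 0,
    hil_backend=None,
    model_id: str = "tcn",
) -> tuple[ObjectiveVector, ResourceReport, object]:
    """Train the architecture and score the four objectives.

    f_error is the validation error rate (1 - accuracy); resource terms come
    from proxies or the HIL backend (falling back to proxies when the
    backend is unavailable). Returns (objectives, resource report, trained
    model); a training failure surfaces as an all-+inf objective vector.
    """
    from .models import TrainingFailure, train_model
    from .models.tcn import TcnConfig

    budget = dict(train_budget or {})
    config = dict(budget)
    if model_id == "tcn":
        config["tcn_config"] = TcnConfig(
            n_filters=cfg["n_filters"],
            kernel=cfg["kernel"],
            dilations=tuple(cfg[f"dilation_{i}"] for i in range(cfg["n_layers"])),
            use_residual=cfg["use_residual"],
        )
    else:
        config.update(cfg)
    X = np.asarray(dataset["X"])
    input_shape = X.shape[1:] if X.ndim == 3 else (X.shape[1],)
    try:
        trained = train_model(model_id, dataset, config, seed=seed)
    except TrainingFailure:
        inf = ObjectiveVector(np.inf, np.inf, np.inf, np.inf)
        return inf, ResourceReport(0, 0, 0), None
    Xv = np.asarray(dataset.get("X_val", dataset["X"]))
    yv = np.asarray(dataset.get("y_val", dataset["y"]))
    f_error = 1.0 - float(np.mean(trained.predict(Xv) == yv))
    if resource_source == "hil":
        try:
            report = hil_measure(hil_backend, trained.model, input_shape)
        except HilUnavailable:
            report = proxy_report(trained.model, input_shape)
    else:
        report = proxy_report(trained.model, input_shape)
    f_flash, f_sram, f_lat = feasibility(report, device)
    return ObjectiveVector(f_error, f_flash, f_sram, f_lat), report, trained


# ------------------------------------------------------------------ search


@dataclass
class NasResult:
    incumbent: dict | None
    incumbent_objectives: ObjectiveVector | None
    pareto_set: list[tuple[dict, ObjectiveVector]]
    trace: list[dict]
    feasible_found: bool


def nas_search(
    space: SearchSpace,
    evaluator: Callable[[dict, int], ObjectiveVector],
    iterations: int,
    lambda_domain: LambdaDomain | None = None,
    batch_size: int = 1,
    seed: int = 0,
    n_candidates: int = 512,
    n_initial: int = 8,
    beta_ucb: float = 4.0,
    batch_strategy: str = "hallucination",
) -> NasResult:
    """Run the Bayesian search for a fixed evaluation budget.

    ``evaluator(cfg, seed) -> ObjectiveVector`` hides training and resource
    measurement (see :func:`evaluate_config`). A fresh scalarization weight
    is drawn per iteration; the incumbent is tracked under the domain's
    reference weight, restricted to budget-feasible models, and is
    non-increasing by construction. Previously evaluated configs are never
    re-suggested; if a finite space is exhausted the search stops early.
    """
    if lambda_domain is None:
        lambda_domain = LambdaDomain()
    if iterations < 1:
        raise ValueError("need at least one iteration")
    rng = np.random.default_rng(seed)
    lam_ref = lambda_domain.reference()

    evaluated: dict[str, tuple[dict, ObjectiveVector]] = {}
    trace: list[dict] = []
    enumerable = space.enumerate(limit=4096)

    def record(cfg: dict, obj: ObjectiveVector, lam: np.ndarray, phase: str) -> None:
        evaluated[config_key(cfg)] = (cfg, obj)
        trace.append(
            {
                "config": cfg,
                "objectives": obj.as_array().tolist(),
                "lambda": np.asarray(lam).tolist(),
                "phase": phase,
            }
        )

    # initial design: uniform random valid configs
    n_init = min(n_initial, iterations)
    while len(evaluated) < n_init:
        cfg = space.sample(rng)
        if config_key(cfg) in evaluated:
            if enumerable is not None and len(evaluated) >= len(enumerable):
                break
            continue
        obj = evaluator(cfg, int(rng.integers(2**31 - 1)))
        record(cfg, obj, lam_ref, "initial")

    surrogate = Surrogate(space, seed=seed)
    while len(evaluated) < iterations:
        if enumerable is not None and len(evaluated) >= len(enumerable):
            break
        lam = lambda_domain.sample(rng)
        cfgs = [c for c, _ in evaluated.values()]
        comps = [o.composite(lam) for _, o in evaluated.values()]
        surrogate.set_observations(cfgs, comps)
        surrogate.fit()

        pool = [
            c
            for c in sample_candidates(space, n_candidates, int(rng.integers(2**31 - 1)))
            if config_key(c) not in evaluated
        ]
        if not pool and enumerable is not None:
            pool = [c for c in enumerable if config_key(c) not in evaluated]
        if not pool:
            break
        uniq: dict[str, dict] = {}
        for c in pool:
            uniq.setdefault(config_key(c), c)
        pool = list(uniq.values())
        b = min(batch_size, len(pool), iterations - len(evaluated))
        picks = batch_suggest(surrogate, pool, b, batch_strategy, beta_ucb, seed=seed)
        for cfg in picks:
            obj = evaluator(cfg, int(rng.integers(2**31 - 1)))
            record(cfg, obj, lam, "search")

    feasible = [(c, o) for c, o in evaluated.values() if o.feasible]
    if not feasible:
        return NasResult(None, None, [], trace, feasible_found=False)
    best_cfg, best_obj = min(feasible, key=lambda co: co[1].composite(lam_ref))
    pareto = [
        (c, o)
        for c, o in feasible
        if not any(dominates(o2, o) for _, o2 in feasible if o2 is not o)
    ]
    return NasResult(best_cfg, best_obj, pareto, trace, feasible_found=True)
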