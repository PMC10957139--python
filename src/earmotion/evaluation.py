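"""Dataset splits, multiclass metrics, DTW class-separability statistics,
window-size and leave-n-out studies, and the fall-detection binary task.

Leave-out splits operate at the participant level: a held-out wearer never
contributes windows to training, which is the generalization test that
matters for wearables. DTW uses the classic dynamic program with the
symmetric match/insert/delete step pattern and Euclidean local cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sstats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .features import features_for_windows
from .imu_core import ImuTrace, Window, sliding_windows
from .models import train_model
from .resources import flash_proxy
from .synthetic import ACTIVITY_CLASSES

__all__ = [
    "SplitPlan",
    "make_split",
    "MetricsReport",
    "multiclass_metrics",
    "dtw_distance",
    "separability_matrix",
    "windows_dataset",
    "leave_one_out_accuracy",
    "window_size_study",
    "fall_detection_study",
    "ks_normality_test",
    "kruskal_wallis",
]


# ------------------------------------------------------------------ splits


@dataclass(frozen=True)
class SplitPlan:
    kind: str = "leave_1_out"  # holdout | leave_1_out | leave_n_out
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_left_out: int = 1
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("holdout", "leave_1_out", "leave_n_out"):
            raise ValueError(f"unknown split kind {self.kind!r}")
        if self.kind == "holdout" and abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("holdout ratios must sum to 1")


def make_split(
    participant_ids: np.ndarray, plan: SplitPlan
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Index sets (train, val, test) per fold.

    Leave-out folds hold out whole participants, drawn without replacement
    across folds; within the retained participants a 90:10 train:val split
    is applied. Holdout ignores participant identity.
    """
    pid = np.asarray(participant_ids)
    rng = np.random.default_rng(plan.seed)
    n = len(pid)
    if plan.kind == "holdout":
        order = rng.permutation(n)
        n_train = int(round(plan.ratios[0] * n))
        n_val = int(round(plan.ratios[1] * n))
        return [
            (
                order[:n_train],
                order[n_train : n_train + n_val],
                order[n_train + n_val :],
            )
        ]
    participants = np.unique(pid)
    n_out = plan.n_left_out if plan.kind == "leave_n_out" else 1
    if n_out >= len(participants):
        raise ValueError("cannot leave out all participants")
    max_folds = len(participants) // n_out
    n_folds = min(plan.n_folds, max_folds)
    held = rng.permutation(participants)[: n_folds * n_out].reshape(n_folds, n_out)
    folds = []
    for fold_out in held:
        test_mask = np.isin(pid, fold_out)
        test_idx = np.flatnonzero(test_mask)
        rest = np.flatnonzero(~test_mask)
        rest = rng.permutation(rest)
        n_val = int(round(0.1 * len(rest)))
        folds.append((rest[n_val:], rest[:n_val], test_idx))
    return folds


# ----------------------------------------------------------------- metrics


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    confusion: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    undefined_classes: tuple[int, ...] = ()


def multiclass_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> MetricsReport:
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if len(y_true) != len(y_pred):
        raise ValueError("label arrays must share one length")
    labels = np.arange(n_classes)
    if y_true.min() < 0 or y_true.max() >= n_classes or y_pred.max() >= n_classes:
        raise ValueError("labels outside [0, n_classes)")
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0.0
    )
    cm = _sk_confusion(y_true, y_pred, labels=labels)
    present = support > 0
    undefined = tuple(int(c) for c in labels[~present])
    return MetricsReport(
        accuracy=float(np.mean(y_true == y_pred)),
        precision=prec,
        recall=rec,
        f1=f1,
        support=support,
        confusion=cm,
        macro_precision=float(prec[present].mean()) if present.any() else float("nan"),
        macro_recall=float(rec[present].mean()) if present.any() else float("nan"),
        macro_f1=float(f1[present].mean()) if present.any() else float("nan"),
        undefined_classes=undefined,
    )


# --------------------------------------------------------------------- DTW


def _dtw_python(a: np.ndarray, b: np.ndarray) -> float:
    n, m = len(a), len(b)
    cost = np.abs(a[:, None] - b[None, :])
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        row = D[i]
        prev = D[i - 1]
        ci = cost[i - 1]
        for j in range(1, m + 1):
            row[j] = ci[j - 1] + min(prev[j - 1], prev[j], row[j - 1])
    return float(D[n, m])


try:  # optional numba kernel: identical algorithm, much faster
    from numba import njit

    @njit(cache=False)
    def _dtw_numba(a, b):  # pragma: no cover - exercised via dtw_distance
        n, m = len(a), len(b)
        D = np.full((n + 1, m + 1), np.inf)
        D[0, 0] = 0.0
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                c = abs(a[i - 1] - b[j - 1])
                best = D[i - 1, j - 1]
                if D[i - 1, j] < best:
                    best = D[i - 1, j]
                if D[i, j - 1] < best:
                    best = D[i, j - 1]
                D[i, j] = c + best
        return D[n, m]

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def dtw_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Dynamic-time-warping distance: symmetric match/insert/delete steps,
    absolute-difference local cost, no windowing constraint."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("DTW inputs must be non-empty")
    if _HAVE_NUMBA:
        return float(_dtw_numba(a, b))
    return _dtw_python(a, b)


def separability_matrix(
    traces: Sequence[ImuTrace],
    labels: Sequence[str] | None = None,
    snapshot_len: int = 400,
    n_snapshots: int = 10,
    seed: int = 0,
    channel: str = "accel_vs",
) -> tuple[np.ndarray, list[str]]:
    """Class x class mean DTW distance over random vector-sum snapshots.

    For each class, ``n_snapshots`` random windows of ``snapshot_len``
    samples are cut from its traces; entry (i, j) is the mean DTW distance
    over all snapshot pairs between class i and class j (within-class pairs
    exclude self-comparisons). Well-separated data shows a diagonal below
    the off-diagonal.
    """
    if labels is None:
        labels = [t.label for t in traces]
    classes = sorted(set(labels), key=lambda c: (ACTIVITY_CLASSES + (c,)).index(c))
    rng = np.random.default_rng(seed)
    snaps: dict[str, list[np.ndarray]] = {c: [] for c in classes}
    by_class: dict[str, list[ImuTrace]] = {c: [] for c in classes}
    for tr, lab in zip(traces, labels):
        by_class[lab].append(tr)
    for c in classes:
        pool = by_class[c]
        if not pool or all(len(t) < snapshot_len for t in pool):
            raise ValueError(f"not enough data to snapshot class {c!r}")
        for _ in range(n_snapshots):
            tr = pool[int(rng.integers(len(pool)))]
            if len(tr) < snapshot_len:
                tr = max(pool, key=len)
            start = int(rng.integers(0, len(tr) - snapshot_len + 1))
            seg = tr.slice(start, start + snapshot_len)
            if channel == "accel_vs":
                snaps[c].append((seg.accel**2).sum(axis=1))
            else:
                snaps[c].append(seg.gyro.sum(axis=1))
    k = len(classes)
    M = np.zeros((k, k))
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            if j < i:
                M[i, j] = M[j, i]
                continue
            dists = [
                dtw_distance(a, b)
                for ai, a in enumerate(snaps[ci])
                for bj, b in enumerate(snaps[cj])
                if not (i == j and ai >= bj)
            ]
            M[i, j] = float(np.mean(dists))
    return M, classes


def ks_normality_test(values: Sequence[float]) -> tuple[float, float]:
    """Kolmogorov-Smirnov test against a fitted normal; (statistic, p)."""
    v = np.asarray(values, float)
    stat, p = sstats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
    return float(stat), float(p)


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    stat, p = sstats.kruskal(*groups)
    return float(stat), float(p)


# ------------------------------------------------------------- studies


def windows_dataset(
    traces: Sequence[ImuTrace],
    window_s: float = 5.0,
    stride_s: float = 0.5,
    representation: str = "raw",
    classes: Sequence[str] = ACTIVITY_CLASSES,
) -> dict:
    """Slice traces into windows and build model-ready arrays.

    representation 'raw' yields (n, T, 6) stacked accel+gyro windows;
    'light' / 'full' yield feature matrices. Returns a dict with X, y,
    participant_ids, classes.
    """
    cls_to_int = {c: i for i, c in enumerate(classes)}
    wins: list[Window] = []
    y: list[int] = []
    pids: list[int] = []
    for tr in traces:
        for w in sliding_windows(tr, window_s, stride_s):
            wins.append(w)
            y.append(cls_to_int[w.label])
            pids.append(tr.participant_id if tr.participant_id is not None else -1)
    if representation == "raw":
        X = np.stack(
            [np.hstack([w.samples.accel, w.samples.gyro]) for w in wins]
        )
    else:
        X, _ = features_for_windows(wins, scheme=representation)
    return {
        "X": X,
        "y": np.asarray(y),
        "participant_ids": np.asarray(pids),
        "classes": tuple(classes),
    }


def leave_one_out_accuracy(
    model_id: str,
    data: dict,
    plan: SplitPlan,
    train_config: dict | None = None,
) -> dict:
    """Participant-level cross-validated accuracy for one model."""
    X, y, pids = data["X"], data["y"], data["participant_ids"]
    folds = make_split(pids, plan)
    accs = []
    reports = []
    for train_idx, val_idx, test_idx in folds:
        assert not set(pids[train_idx]) & set(pids[test_idx])
        trained = train_model(
            model_id,
            {
                "X": X[train_idx],
                "y": y[train_idx],
                "X_val": X[val_idx] if len(val_idx) else None,
                "y_val": y[val_idx] if len(val_idx) else None,
            },
            train_config,
            seed=plan.seed,
        )
        pred = trained.predict(X[test_idx])
        rep = multiclass_metrics(y[test_idx], pred, n_classes=len(data["classes"]))
        accs.append(rep.accuracy)
        reports.append(rep)
    return {
        "fold_accuracies": accs,
        "mean_accuracy": float(np.mean(accs)),
        "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        "reports": reports,
    }


def window_size_study(
    model_id: str,
    traces: Sequence[ImuTrace],
    sizes_s: Sequence[float],
    plan: SplitPlan,
    representation: str = "light",
    train_config: dict | None = None,
) -> list[dict]:
    """Leave-out accuracy as a function of window size.

    Also reports accuracy normalized by the model's maximum across sizes.
    """
    rows = []
    for size in sizes_s:
        data = windows_dataset(traces, window_s=size, representation=representation)
        res = leave_one_out_accuracy(model_id, data, plan, train_config)
        rows.append(
            {"window_s": size, "mean_accuracy": res["mean_accuracy"], "sd": res["sd_accuracy"]}
        )
    best = max(r["mean_accuracy"] for r in rows) or 1.0
    for r in rows:
        r["normalized_accuracy"] = r["mean_accuracy"] / best
    return rows


def fall_detection_study(
    traces: Sequence[ImuTrace],
    model_ids: Sequence[str] = ("bonsai", "protonn"),
    plan: SplitPlan = SplitPlan(n_folds=3),
    window_s: float = 5.0,
    train_config: dict | None = None,
) -> dict:
    """Binary fall vs non-fall task on the lightweight feature scheme.

    Relabels class F against everything else, trains the requested feature
    models, and reports leave-out accuracy plus the flash-proxy model size.
    """
    if not any(t.label == "F" for t in traces):
        raise ValueError("dataset contains no fall traces")
    data = windows_dataset(traces, window_s=window_s, representation="light")
    y_bin = (np.asarray([data["classes"][i] for i in data["y"]]) == "F").astype(int)
    bin_data = {
        "X": data["X"],
        "y": y_bin,
        "participant_ids": data["participant_ids"],
        "classes": ("non-fall", "fall"),
    }
    out = {}
    for mid in model_ids:
        res = leave_one_out_accuracy(mid, bin_data, plan, train_config)
        trained = train_model(mid, {"X": data["X"], "y": y_bin}, train_config, seed=plan.seed)
        degenerate = any(r.undefined_classes for r in res["reports"])
        out[mid] = {
            "mean_accuracy": res["mean_accuracy"],
            "sd_accuracy": res["sd_accuracy"],
            "flash_bytes": flash_proxy(trained.model),
            "degenerate_folds": degenerate,
        }
    return out
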