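"""Dataset splitting, network training, and the classification metric suite.

The evaluation protocol: 30% of spectra are randomly held out as the
prediction set, the remaining 70% split 3:1 into training and validation
(stratified by class so every mixture class appears in every subset); the
model with the best validation accuracy is kept. Reported quantities are
overall accuracy per subset (ACC_T / ACC_V / ACC_P) and one-vs-rest
per-class Precision, Recall and F1 on the prediction set:

    Precision = TP / (TP + FP)        Recall = TP / (TP + FN)
    F1 = 2 * Precision * Recall / (Precision + Recall)

with TP/TN/FP/FN read off the confusion matrix (rows = true class,
columns = predicted class) and overall ACC = trace / total. All percentages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .nets import Network, clone_network
from .nn import Adam, softmax_cross_entropy
from .simulate import CLASSES, MixtureSample, flatten_spectra
from .spectra import DEFAULT_GRID, RamanSpectrum, WavenumberGrid, normalize, resample

__all__ = [
    "DatasetSplit",
    "ConfusionMatrix",
    "ClassMetrics",
    "ClassificationReport",
    "TrainingConfig",
    "TrainResult",
    "split_dataset",
    "per_class_counts",
    "metrics",
    "dataset_to_arrays",
    "train",
    "evaluate",
    "evaluation_summary",
    "write_report",
]


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    """Disjoint index partition into training / validation / prediction."""

    training: np.ndarray
    validation: np.ndarray
    prediction: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [set(self.training.tolist()), set(self.validation.tolist()),
                set(self.prediction.tolist())]
        n = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != n:
            raise ValueError("split subsets overlap")

    @property
    def n_total(self) -> int:
        return len(self.training) + len(self.validation) + len(self.prediction)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "training": self.training.tolist(),
            "validation": self.validation.tolist(),
            "prediction": self.prediction.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetSplit":
        return cls(
            training=np.asarray(d["training"], dtype=int),
            validation=np.asarray(d["validation"], dtype=int),
            prediction=np.asarray(d["prediction"], dtype=int),
            seed=int(d.get("seed", 0)),
        )


def _apportion(counts: Sequence[int], fraction: float, total: int) -> list[int]:
    """Largest-remainder allocation of ``total`` slots across classes in
    proportion to ``fraction * count``; deterministic tie-break by class order."""
    shares = [fraction * c for c in counts]
    base = [min(math.floor(s), c) for s, c in zip(shares, counts)]
    remainder = total - sum(base)
    order = sorted(
        range(len(counts)),
        key=lambda k: (-(shares[k] - base[k]), k),
    )
    quotas = list(base)
    i = 0
    while remainder > 0:
        k = order[i % len(order)]
        if quotas[k] < counts[k]:
            quotas[k] += 1
            remainder -= 1
        i += 1
    return quotas


def split_dataset(
    labels: Sequence[str],
    seed: int = 0,
    group_ids: Sequence[str] | None = None,
) -> DatasetSplit:
    """Stratified random partition: 30% prediction, remainder 3:1
    training:validation, per class, deterministic given ``seed``.

    Per-class subset sizes use largest-remainder apportionment so the global
    totals are exactly round(0.30 N) prediction and round(0.25 (N - pred))
    validation (e.g. 120 / 210 / 70 for N = 400). If ``group_ids`` is given,
    whole groups (e.g. all replicates of one physical sample) are assigned to
    a single subset — the stricter no-leakage variant.
    """
    labels = list(labels)
    n = len(labels)
    if n < 8:
        raise ValueError("need at least 8 spectra to split")
    class_names = list(dict.fromkeys(labels))
    rng = np.random.default_rng(seed)

    if group_ids is not None:
        return _split_by_group(labels, list(group_ids), class_names, rng, seed)

    idx_by_class = {c: np.flatnonzero(np.asarray(labels, dtype=object) == c) for c in class_names}
    counts = [len(idx_by_class[c]) for c in class_names]
    total_pred = int(round(0.30 * n))
    pred_quota = _apportion(counts, 0.30, total_pred)
    rem_counts = [c - q for c, q in zip(counts, pred_quota)]
    total_val = int(round(0.25 * (n - total_pred)))
    val_quota = _apportion(rem_counts, 0.25, total_val)

    train_idx, val_idx, pred_idx = [], [], []
    for k, c in enumerate(class_names):
        if pred_quota[k] == 0 or val_quota[k] == 0 or rem_counts[k] - val_quota[k] == 0:
            raise ValueError(
                f"class {c!r} has too few spectra ({counts[k]}) to appear in all "
                "three subsets"
            )
        perm = rng.permutation(idx_by_class[c])
        p, v = pred_quota[k], val_quota[k]
        pred_idx.extend(perm[:p])
        val_idx.extend(perm[p : p + v])
        train_idx.extend(perm[p + v :])

    return DatasetSplit(
        training=np.sort(np.asarray(train_idx, dtype=int)),
        validation=np.sort(np.asarray(val_idx, dtype=int)),
        prediction=np.sort(np.asarray(pred_idx, dtype=int)),
        seed=seed,
    )


def _split_by_group(
    labels: list[str],
    group_ids: list[str],
    class_names: list[str],
    rng: np.random.Generator,
    seed: int,
) -> DatasetSplit:
    if len(group_ids) != len(labels):
        raise ValueError("group_ids length must match labels")
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(group_ids):
        groups.setdefault(g, []).append(i)
    train_idx, val_idx, pred_idx = [], [], []
    for c in class_names:
        cls_groups = [g for g in groups if labels[groups[g][0]] == c]
        if len(cls_groups) < 3:
            raise ValueError(f"class {c!r} needs at least 3 groups for a group split")
        perm = rng.permutation(len(cls_groups))
        cls_groups = [cls_groups[i] for i in perm]
        n_cls = sum(len(groups[g]) for g in cls_groups)
        target_pred = 0.30 * n_cls
        target_val = 0.25 * (n_cls - target_pred)
        acc = 0
        for g in cls_groups:
            size = len(groups[g])
            if acc < target_pred:
                pred_idx.extend(groups[g])
            elif acc < target_pred + target_val:
                val_idx.extend(groups[g])
            else:
                train_idx.extend(groups[g])
            acc += size
    return DatasetSplit(
        training=np.sort(np.asarray(train_idx, dtype=int)),
        validation=np.sort(np.asarray(val_idx, dtype=int)),
        prediction=np.sort(np.asarray(pred_idx, dtype=int)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Confusion matrix and metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected {k}x{k} matrix, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("confusion-matrix counts must be non-negative")

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int], classes: Sequence[str]
    ) -> "ConfusionMatrix":
        k = len(classes)
        counts = np.zeros((k, k), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[t, p] += 1
        return cls(counts=counts, classes=list(classes))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def per_class_counts(cm: ConfusionMatrix, k: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, TN, FP, FN) for class index ``k``."""
    tp = int(cm.counts[k, k])
    fp = int(cm.counts[:, k].sum()) - tp
    fn = int(cm.counts[k, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, tn, fp, fn


@dataclass
class ClassMetrics:
    """One-vs-rest metrics for one class, in percent. A metric whose
    denominator is zero is ``None`` (undefined), never silently 0."""

    precision: float | None
    recall: float | None
    f1: float | None
    tp: int
    tn: int
    fp: int
    fn: int


@dataclass
class ClassificationReport:
    """Overall accuracy (%) plus per-class one-vs-rest metrics."""

    accuracy: float
    per_class: dict[str, ClassMetrics]
    confusion: ConfusionMatrix

    def to_dict(self, ndigits: int = 2) -> dict:
        def r(x):
            return None if x is None else round(x, ndigits)

        return {
            "accuracy": r(self.accuracy),
            "per_class": {
                c: {
                    "precision": r(m.precision),
                    "recall": r(m.recall),
                    "f1": r(m.f1),
                    "tp": m.tp,
                    "tn": m.tn,
                    "fp": m.fp,
                    "fn": m.fn,
                }
                for c, m in self.per_class.items()
            },
            "confusion_matrix": self.confusion.counts.tolist(),
            "classes": list(self.confusion.classes),
        }


def metrics(cm: ConfusionMatrix) -> ClassificationReport:
    """Overall ACC (trace/total) and per-class Precision/Recall/F1 from the
    confusion matrix. Percentages at full float precision; round at
    serialisation time."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * np.trace(cm.counts) / total
    per_class: dict[str, ClassMetrics] = {}
    for k, name in enumerate(cm.classes):
        tp, tn, fp, fn = per_class_counts(cm, k)
        precision = 100.0 * tp / (tp + fp) if tp + fp > 0 else None
        recall = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
        if precision is None or recall is None:
            f1 = None
        elif precision + recall == 0:
            f1 = 0.0  # both defined and zero: harmonic-mean limit convention
        else:
            f1 = 2.0 * precision * recall / (precision + recall)
        per_class[name] = ClassMetrics(precision, recall, f1, tp, tn, fp, fn)
    return ClassificationReport(accuracy=accuracy, per_class=per_class, confusion=cm)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (inputs and output in %)."""
    if precision + recall == 0:
        raise ValueError("F1 undefined when precision + recall = 0")
    return 2.0 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# Arrays for the networks
# ---------------------------------------------------------------------------

def dataset_to_arrays(
    data: Sequence[MixtureSample] | Sequence[RamanSpectrum],
    grid: WavenumberGrid = DEFAULT_GRID,
    normalization: str = "minmax",
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Resample + normalise labelled spectra into (X, y, class_names,
    sample_ids); X is (n_spectra, n_points), y integer class indices."""
    if data and isinstance(data[0], MixtureSample):
        spectra = flatten_spectra(data)  # type: ignore[arg-type]
    else:
        spectra = list(data)  # type: ignore[assignment]
    if not spectra:
        raise ValueError("no spectra")
    labels = [s.label for s in spectra]
    if any(l is None for l in labels):
        raise ValueError("all spectra must carry a class label")
    if set(labels) <= set(CLASSES):
        class_names = [c for c in CLASSES if c in set(labels)]
    else:
        class_names = sorted(set(labels))
    class_index = {c: i for i, c in enumerate(class_names)}
    X = np.empty((len(spectra), grid.n_points))
    for i, s in enumerate(spectra):
        if s.grid != grid:
            s = resample(s, grid)
        X[i] = normalize(s, normalization).intensities
    y = np.asarray([class_index[l] for l in labels], dtype=int)
    sample_ids = [s.sample_id for s in spectra]
    return X, y, class_names, sample_ids


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 30  # epochs without validation-accuracy improvement
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "seed": self.seed,
        }


@dataclass
class TrainResult:
    network: Network
    history: pd.DataFrame  # columns: epoch, loss, acc_train, acc_val
    best_epoch: int


def _accuracy(network: Network, X: np.ndarray, y: np.ndarray) -> float:
    return float(100.0 * (network.predict(X) == y).mean())


def train(
    network: Network,
    X: np.ndarray,
    y: np.ndarray,
    split: DatasetSplit,
    config: TrainingConfig | None = None,
) -> TrainResult:
    """Minimise softmax cross-entropy on the training subset with Adam;
    keep the epoch with the best validation accuracy (early stopping)."""
    config = config or TrainingConfig()
    if X.shape[1] != network.config.input_length:
        raise ValueError(
            f"spectra have {X.shape[1]} points but the network expects "
            f"{network.config.input_length}"
        )
    rng = np.random.default_rng(config.seed)
    opt = Adam(network.params(), lr=config.learning_rate)
    tr, va = split.training, split.validation
    best_val, best_epoch, best_net, wait = -1.0, -1, None, 0
    rows = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(tr)
        losses = []
        for i in range(0, len(order), config.batch_size):
            bidx = order[i : i + config.batch_size]
            logits = network.forward(X[bidx][:, None, :], training=True)
            loss, dlogits = softmax_cross_entropy(logits, y[bidx])
            opt.zero_grad()
            network.backward(dlogits)
            opt.step()
            losses.append(loss)
        acc_t = _accuracy(network, X[tr], y[tr])
        acc_v = _accuracy(network, X[va], y[va])
        rows.append(
            {"epoch": epoch, "loss": float(np.mean(losses)),
             "acc_train": acc_t, "acc_val": acc_v}
        )
        if acc_v > best_val:
            best_val, best_epoch, wait = acc_v, epoch, 0
            best_net = clone_network(network)
        else:
            wait += 1
            if wait >= config.patience:
                break
    assert best_net is not None
    return TrainResult(network=best_net, history=pd.DataFrame(rows), best_epoch=best_epoch)


def evaluate(
    network: Network,
    X: np.ndarray,
    y: np.ndarray,
    split: DatasetSplit,
    class_names: Sequence[str],
) -> dict[str, ClassificationReport]:
    """Classification report for each subset (argmax of the softmax output)."""
    reports = {}
    for name, idx in (
        ("training", split.training),
        ("validation", split.validation),
        ("prediction", split.prediction),
    ):
        if len(idx) == 0:
            raise ValueError(f"{name} subset is empty")
        y_pred = network.predict(X[idx])
        cm = ConfusionMatrix.from_predictions(y[idx], y_pred, class_names)
        reports[name] = metrics(cm)
    return reports


def evaluation_summary(
    reports: dict[str, ClassificationReport],
    architecture: str = "",
    seed: int | None = None,
    ndigits: int = 2,
) -> dict:
    """Flat report: ACC per subset + per-class metrics on the prediction set."""
    pred = reports["prediction"].to_dict(ndigits)
    return {
        "architecture": architecture,
        "seed": seed,
        "acc_t": round(reports["training"].accuracy, ndigits),
        "acc_v": round(reports["validation"].accuracy, ndigits),
        "acc_p": round(reports["prediction"].accuracy, ndigits),
        "per_class": [
            {"class": c, **{k: v for k, v in m.items()}}
            for c, m in pred["per_class"].items()
        ],
        "confusion_matrix": pred["confusion_matrix"],
        "classes": pred["classes"],
    }


def write_report(summary: dict, json_path: str | Path, csv_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")
    if csv_path is not None:
        pd.DataFrame(summary["per_class"]).to_csv(csv_path, index=False)
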