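"""Confusion-matrix metrics, ROC/AUC, cross-validation, and report export.

Metrics follow the percent-scale likelihood-ratio formulation:
+LR = sensitivity / (100 - specificity) and -LR = (100 - sensitivity) /
specificity.  Undefined ratios (zero denominators) are returned as flagged
infinities / NaN rather than raising.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import models as M
from .dataset import FoldPlan
from .models import ConvergenceTrace

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "RocCurve",
    "ConvergenceTrace",
    "confusion_from_predictions",
    "compute_metrics",
    "roc_curve",
    "cross_validate",
    "export_report",
    "SingleClassRocError",
]


class SingleClassRocError(ValueError):
    """ROC requires both classes among the labels."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Percent-scale confusion metrics plus unitless likelihood ratios."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    plr: float
    nlr: float


def confusion_from_predictions(labels: np.ndarray, predicted: np.ndarray) -> ConfusionMatrix:
    labels = np.asarray(labels).astype(int)
    predicted = np.asarray(predicted).astype(int)
    if labels.shape != predicted.shape:
        raise ValueError(f"shape mismatch: {labels.shape} vs {predicted.shape}")
    return ConfusionMatrix(
        tp=int(np.sum((labels == 1) & (predicted == 1))),
        fp=int(np.sum((labels == 0) & (predicted == 1))),
        tn=int(np.sum((labels == 0) & (predicted == 0))),
        fn=int(np.sum((labels == 1) & (predicted == 0))),
    )


def _ratio(num: float, den: float) -> float:
    """Guarded division: x/0 -> +inf for x > 0, NaN for 0/0."""
    if den == 0.0:
        return math.inf if num > 0 else math.nan
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Percent-scale metrics from a confusion matrix.

    Division by zero never raises: the affected metric comes back as inf/NaN
    (e.g. +LR of a perfectly specific classifier is +inf).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total * 100.0
    precision = _ratio(cm.tp, cm.tp + cm.fp) * 100.0
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn) * 100.0
    specificity = _ratio(cm.tn, cm.fp + cm.tn) * 100.0
    f1 = _ratio(2.0 * precision * sensitivity, precision + sensitivity)
    plr = _ratio(sensitivity, 100.0 - specificity)
    nlr = _ratio(100.0 - sensitivity, specificity)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        plr=plr,
        nlr=nlr,
    )


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float, float]:
    """+LR and -LR from percent-scale sensitivity and specificity."""
    return (
        _ratio(sensitivity, 100.0 - specificity),
        _ratio(100.0 - sensitivity, specificity),
    )


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(labels: np.ndarray, probabilities: np.ndarray) -> RocCurve:
    """ROC with tie grouping and trapezoidal AUC.

    One (fpr, tpr) point per distinct score, descending; samples with equal
    scores enter together.  Endpoints (0,0) and (1,1) are always present.
    """
    y = np.asarray(labels).astype(int).ravel()
    p = np.asarray(probabilities, dtype=float).ravel()
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError("probabilities must be finite")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise SingleClassRocError("ROC needs both classes present")

    order = np.argsort(-p, kind="stable")
    p_sorted = p[order]
    y_sorted = y[order]
    # last index of each tie group
    distinct = np.nonzero(np.diff(p_sorted))[0]
    group_ends = np.r_[distinct, y_sorted.size - 1]
    cum_tp = np.cumsum(y_sorted)[group_ends]
    cum_fp = np.cumsum(1 - y_sorted)[group_ends]
    tpr = np.r_[0.0, cum_tp / n_pos]
    fpr = np.r_[0.0, cum_fp / n_neg]
    thresholds = np.r_[math.inf, p_sorted[group_ends]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def cross_validate(
    spec: M.ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    fold_plan: FoldPlan,
    train_config: M.TrainConfig | None = None,
    window_length: int | None = None,
) -> tuple[list[MetricsReport], float]:
    """Train/evaluate once per fold; returns per-fold metrics and mean accuracy.

    Fold ``f`` trains on all other folds with a seed derived as
    ``base_seed + f`` and tests on fold ``f``.
    """
    train_config = train_config or M.TrainConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int).ravel()
    if window_length is None:
        window_length = X.shape[1]
    reports: list[MetricsReport] = []
    for fold in range(fold_plan.k):
        test_mask = fold_plan.assignment == fold
        ytr = y[~test_mask]
        if np.unique(ytr).size < 2:
            raise M.SingleClassError(f"fold {fold}: training portion has one class")
        fold_config = M.TrainConfig(
            loss=train_config.loss,
            optimizer=train_config.optimizer,
            learning_rate=train_config.learning_rate,
            epochs=train_config.epochs,
            batch_size=train_config.batch_size,
            seed=train_config.seed + fold,
            classification_threshold=train_config.classification_threshold,
        )
        model = M.build_model(spec, window_length, seed=fold_config.seed)
        model, _ = M.train(model, (X[~test_mask], ytr), None, fold_config)
        _, pred = M.predict(model, X[test_mask], fold_config.classification_threshold)
        reports.append(compute_metrics(confusion_from_predictions(y[test_mask], pred)))
    mean_accuracy = float(np.mean([r.accuracy for r in reports]))
    return reports, mean_accuracy


def export_report(
    out_dir: str | Path,
    config: dict,
    metrics: MetricsReport | None = None,
    confusion: ConfusionMatrix | None = None,
    roc: RocCurve | None = None,
    trace: ConvergenceTrace | None = None,
) -> list[Path]:
    """Write run artifacts as columnar text plus a JSON manifest.

    Data files carry no timestamps, so re-exporting the same artifacts is
    byte-identical.
    """
    out_dir = Path(out_dir)
    if not out_dir.parent.exists():
        raise FileNotFoundError(f"parent directory missing: {out_dir.parent}")
    out_dir.mkdir(exist_ok=True)
    written: list[Path] = []

    def emit(name: str, text: str) -> None:
        path = out_dir / name
        path.write_text(text)
        written.append(path)

    emit("manifest.json", json.dumps({"config": config}, indent=2, sort_keys=True) + "\n")
    if confusion is not None:
        emit(
            "confusion.tsv",
            "tp\tfp\ttn\tfn\n" f"{confusion.tp}\t{confusion.fp}\t{confusion.tn}\t{confusion.fn}\n",
        )
    if metrics is not None:
        lines = ["metric\tvalue"]
        lines += [f"{k}\t{v:.6g}" for k, v in asdict(metrics).items()]
        emit("metrics.tsv", "\n".join(lines) + "\n")
    if roc is not None:
        lines = ["threshold\tfpr\ttpr"]
        lines += [
            f"{t:.6g}\t{f:.6g}\t{s:.6g}"
            for t, f, s in zip(roc.thresholds, roc.fpr, roc.tpr)
        ]
        lines.append(f"# auc\t{roc.auc:.6g}")
        emit("roc.tsv", "\n".join(lines) + "\n")
    if trace is not None:
        lines = ["epoch\ttrain_loss\ttrain_acc\tval_loss\tval_acc"]
        for i in range(trace.n_epochs()):
            vl = f"{trace.val_loss[i]:.6g}" if trace.val_loss else "-"
            va = f"{trace.val_acc[i]:.6g}" if trace.val_acc else "-"
            lines.append(
                f"{i}\t{trace.train_loss[i]:.6g}\t{trace.train_acc[i]:.6g}\t{vl}\t{va}"
            )
        emit("trace.tsv", "\n".join(lines) + "\n")
    return written
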