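"""Cross-validation, the five classification metrics, and significance tests.

Each (variant, segment-duration) combination is scored by stratified
k-fold cross-validation: a fresh model is trained on k-1 folds and its
held-out fold is summarized as accuracy, sensitivity (recall),
specificity, precision and F1 — all percentages derived from the
confusion counts with ictal as the positive class.  Fold results are
aggregated as mean +/- sample standard deviation, and groups of fold
metrics are compared across models with the Kruskal–Wallis H test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np

from .dataset import SegmentDataset
from .nn.functional import ShapeError
from .nn.models import ModelConfig, build_model
from .training import TrainingConfig, train_model
from .types import SdcaeError

__all__ = [
    "ConfusionCounts",
    "FoldMetrics",
    "CVSummary",
    "UndefinedMetricWarning",
    "confusion_from_probs",
    "compute_metrics",
    "cross_validate",
    "kruskal_wallis",
    "render_report",
]

METRICS = ("accuracy", "sensitivity", "specificity", "precision", "f1")


class UndefinedMetricWarning(UserWarning):
    """A metric's denominator was zero; the value is reported as NaN."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class FoldMetrics:
    """The five evaluation metrics for one fold, as percentages."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion_from_probs(
    y_true: np.ndarray, y_prob: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Tally confusion counts; a probability equal to the threshold predicts
    the positive (ictal) class."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if y_true.shape != y_prob.shape:
        raise ShapeError(f"length mismatch: {y_true.shape} vs {y_prob.shape}")
    pred = y_prob >= threshold
    pos = y_true == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", UndefinedMetricWarning,
                      stacklevel=3)
        return float("nan")
    return 100.0 * num / den


def compute_metrics(c: ConfusionCounts) -> FoldMetrics:
    """Accuracy, sensitivity, specificity, precision and F1 in percent.

    Any ratio with a zero denominator is NaN with an
    :class:`UndefinedMetricWarning`, never silently zero.
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = _ratio(c.tp + c.tn, c.total, "accuracy")
    sensitivity = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    specificity = _ratio(c.tn, c.tn + c.fp, "specificity")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        warnings.warn("f1 undefined", UndefinedMetricWarning, stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    return FoldMetrics(accuracy, sensitivity, specificity, precision, f1)


@dataclass
class CVSummary:
    """Fold metrics and their mean +/- sample standard deviation."""

    variant: str
    duration_s: int
    fold_metrics: list[FoldMetrics] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(m, metric) for m in self.fold_metrics]))

    def std(self, metric: str) -> float:
        vals = [getattr(m, metric) for m in self.fold_metrics]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def as_row(self) -> dict:
        row: dict = {"duration_s": self.duration_s, "variant": self.variant}
        for m in METRICS:
            row[f"{m}_mean"] = self.mean(m)
            row[f"{m}_std"] = self.std(m)
        return row


def cross_validate(
    datasets: dict[int, SegmentDataset],
    variants: list[str],
    train_config: TrainingConfig,
    config_for: "callable | None" = None,
    base_seed: int = 0,
    trainer: "callable | None" = None,
) -> list[CVSummary]:
    """Full stratified k-fold protocol over a (variant x duration) grid.

    ``datasets`` maps segment duration to a fold-assigned dataset.  For each
    combination and each fold, a model is built from a fresh fold-derived
    seed, trained on the other folds, and scored on the held-out fold.
    ``config_for(variant, duration)`` supplies the architecture (defaults to
    the full-scale one); ``trainer(model, X, y)`` may replace the training
    loop (used to stub the classifier in protocol tests).
    """
    if config_for is None:
        config_for = lambda variant, duration: ModelConfig(variant=variant, duration_s=duration)
    summaries: list[CVSummary] = []
    for duration, ds in sorted(datasets.items()):
        if ds.fold_of is None:
            raise SdcaeError("dataset lacks fold assignments")
        folds = np.unique(ds.fold_of)
        for variant in variants:
            summary = CVSummary(variant=variant, duration_s=duration)
            for fold in folds:
                test_mask = ds.fold_of == fold
                X_tr, y_tr = ds.X[~test_mask], ds.y[~test_mask]
                X_te, y_te = ds.X[test_mask], ds.y[test_mask]
                fold_seed = base_seed + 1000 * int(fold)
                model = build_model(config_for(variant, duration), seed=fold_seed)
                if trainer is not None:
                    trainer(model, X_tr, y_tr)
                else:
                    from dataclasses import replace
                    train_model(model, X_tr, y_tr, replace(train_config, seed=fold_seed))
                prob = model.predict_proba(X_te)
                summary.fold_metrics.append(compute_metrics(confusion_from_probs(y_te, prob)))
            summaries.append(summary)
    return summaries


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; p from the chi-square
    approximation with (groups - 1) degrees of freedom.

    By convention, identical values across all groups give (0, 1).
    """
    from scipy import stats

    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs at least two values")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def render_report(summaries: list[CVSummary]):
    """Tabulate summaries: one row per (duration, variant), metric mean/std
    columns; NaNs render as NA in the CSV."""
    import pandas as pd

    if not summaries:
        raise ValueError("no summaries to render")
    return pd.DataFrame([s.as_row() for s in summaries])
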