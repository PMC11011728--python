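"""Evaluation machinery: confusion matrix, weighted metrics, k-fold CV
bookkeeping and the paired t-test used to compare two models fold-by-fold.

Conventions: weighted precision/recall average the per-phase values with the
true-class supports as weights (so weighted recall coincides with accuracy);
a phase with zero predicted positives gets precision 0.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
from scipy import stats as sps
from sklearn.metrics import confusion_matrix as _sk_confusion

from .exceptions import DegenerateInputError

N_PHASES = 7


@dataclasses.dataclass
class EvalReport:
    confusion: np.ndarray
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    per_phase: list  # (precision, recall, support) per phase
    fold_id: int | None = None

    def to_dict(self) -> dict:
        return {
            "fold_id": self.fold_id,
            "confusion": np.asarray(self.confusion).tolist(),
            "accuracy": self.accuracy,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "per_phase": [list(map(float, row[:2])) + [int(row[2])]
                          for row in self.per_phase],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclasses.dataclass
class FoldPlan:
    k: int
    assignment: dict  # video_id -> fold_id
    seed: int

    def fold_videos(self, fold_id: int) -> list:
        return [v for v, f in self.assignment.items() if f == fold_id]

    def train_videos(self, fold_id: int) -> list:
        return [v for v, f in self.assignment.items() if f != fold_id]


def confusion_matrix(y_true, y_pred, n_classes: int = N_PHASES) -> np.ndarray:
    """Count matrix with rows = true phase, columns = predicted phase."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must share length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise IndexError(f"{name} contains labels outside [0, {n_classes})")
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


def classification_metrics(confusion) -> dict:
    """Accuracy and support-weighted precision/recall from a confusion matrix."""
    cm = np.asarray(confusion, dtype=np.float64)
    total = cm.sum()
    if total == 0:
        raise DegenerateInputError("empty confusion matrix")
    tp = np.diag(cm)
    support = cm.sum(axis=1)  # true-class counts
    predicted = cm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
    if ((predicted == 0) & (support > 0)).any():
        warnings.warn(
            "phase with zero predicted positives: precision set to 0",
            stacklevel=2,
        )
    weights = support / total
    return {
        "accuracy": float(tp.sum() / total),
        "weighted_precision": float((weights * precision).sum()),
        "weighted_recall": float((weights * recall).sum()),
        "per_phase": [
            (float(p), float(r), int(s))
            for p, r, s in zip(precision, recall, support)
        ],
    }


def evaluate_predictions(y_true, y_pred, fold_id=None,
                         n_classes: int = N_PHASES) -> EvalReport:
    cm = confusion_matrix(y_true, y_pred, n_classes)
    m = classification_metrics(cm)
    return EvalReport(confusion=cm, fold_id=fold_id, **m)


def kfold_split(video_ids, k: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded shuffle + round-robin assignment of whole videos to k folds."""
    video_ids = list(video_ids)
    if k > len(video_ids):
        raise ValueError(f"k={k} exceeds number of videos {len(video_ids)}")
    rng = np.random.default_rng(seed)
    order = list(video_ids)
    rng.shuffle(order)
    return FoldPlan(
        k=k, assignment={v: i % k for i, v in enumerate(order)}, seed=seed
    )


_METRICS = ("accuracy", "weighted_precision", "weighted_recall")


def aggregate_folds(reports) -> dict:
    """Sample mean and sd (n-1 denominator) of each metric across folds."""
    reports = list(reports)
    if len(reports) < 2:
        raise ValueError("need >= 2 fold reports for a standard deviation")
    out = {}
    for m in _METRICS:
        vals = np.array([getattr(r, m) for r in reports], dtype=np.float64)
        out[m] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    return out


@dataclasses.dataclass
class PairedTTestResult:
    t_statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False


def paired_t_test(a, b, alpha: float = 0.05) -> PairedTTestResult:
    """Two-sided paired t-test on per-fold metrics of two models.

    t = mean(d) / (sd(d)/sqrt(n)) on differences d = a - b, with n-1 degrees
    of freedom.  Zero-variance differences make the statistic undefined; the
    result is flagged degenerate instead of raising.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired vectors must share length")
    if a.size < 2:
        raise ValueError("need >= 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        return PairedTTestResult(
            t_statistic=np.nan, p_value=np.nan, significant=False,
            degenerate=True,
        )
    t, p = sps.ttest_rel(a, b)
    return PairedTTestResult(
        t_statistic=float(t), p_value=float(p), significant=bool(p < alpha)
    )
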