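"""Multi-label evaluation: Hamming distance, exact accuracies,
confusion-derived per-label and pooled metrics, rank-statistic AUC,
first-access accuracy and the facility-attendance lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass
class ConfusionCounts:
    """Per-label confusion-matrix entries; arrays of length ``n_labels``."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def n_samples(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0])


def confusion_counts(Y: np.ndarray, Y_hat: np.ndarray) -> ConfusionCounts:
    Y = np.asarray(Y, dtype=bool)
    Y_hat = np.asarray(Y_hat, dtype=bool)
    if Y.shape != Y_hat.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {Y_hat.shape}")
    return ConfusionCounts(
        tp=(Y & Y_hat).sum(axis=0),
        fp=(~Y & Y_hat).sum(axis=0),
        tn=(~Y & ~Y_hat).sum(axis=0),
        fn=(Y & ~Y_hat).sum(axis=0),
    )


def hamming_distance(y: np.ndarray, y_hat: np.ndarray) -> int:
    """Number of label positions where prediction and truth disagree."""
    y, y_hat = np.asarray(y), np.asarray(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    return int((y != y_hat).sum())


def mean_hamming_distance(Y: np.ndarray, Y_hat: np.ndarray) -> float:
    """Average number of missed labels per window."""
    Y, Y_hat = np.asarray(Y), np.asarray(Y_hat)
    if Y.shape != Y_hat.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {Y_hat.shape}")
    return float((Y != Y_hat).sum(axis=1).mean())


def exact_accuracy(Y: np.ndarray, Y_hat: np.ndarray,
                   ignore_last: bool = False) -> float:
    """Fraction of samples whose whole label vector is predicted exactly;
    with ``ignore_last`` the final (other-facilities) label is dropped."""
    Y, Y_hat = np.asarray(Y), np.asarray(Y_hat)
    if len(Y) == 0:
        raise ValueError("empty evaluation set")
    if ignore_last:
        Y, Y_hat = Y[:, :-1], Y_hat[:, :-1]
    return float((Y == Y_hat).all(axis=1).mean())


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic:
    the probability that a random positive outscores a random negative,
    ties counted half.  NaN when the labels are constant."""
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(np.asarray(scores, dtype=np.float64))
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def per_label_metrics(counts: ConfusionCounts,
                      scores: np.ndarray | None = None,
                      labels: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Accuracy, precision, recall, F1 and (given scores) AUC per label.

    Undefined precision/recall (empty denominator) is reported as 0 with
    the label index listed under ``undefined``; AUC is NaN for constant
    labels.
    """
    tp, fp, tn, fn = (counts.tp.astype(float), counts.fp.astype(float),
                      counts.tn.astype(float), counts.fn.astype(float))
    n = tp + fp + tn + fn
    undefined = sorted(set(np.flatnonzero(tp + fp == 0).tolist())
                       | set(np.flatnonzero(tp + fn == 0).tolist()))
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    with np.errstate(invalid="ignore"):
        accuracy = np.where(n > 0, (tp + tn) / np.maximum(n, 1), np.nan)
    out = {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "undefined": np.asarray(undefined, dtype=int),
    }
    if scores is not None and labels is not None:
        out["auc"] = np.array([auc_score(scores[:, j], labels[:, j])
                               for j in range(scores.shape[1])])
    return out


def overall_metrics(counts: ConfusionCounts,
                    scores: np.ndarray | None = None,
                    labels: np.ndarray | None = None) -> dict[str, float]:
    """Pooled (micro) precision/recall/F1/AUC over all labels, with macro
    variants alongside so the averaging choice stays visible."""
    tp, fp, fn = counts.tp.sum(), counts.fp.sum(), counts.fn.sum()
    micro_p = tp / (tp + fp) if tp + fp else 0.0
    micro_r = tp / (tp + fn) if tp + fn else 0.0
    micro_f1 = (2 * micro_p * micro_r / (micro_p + micro_r)
                if micro_p + micro_r else 0.0)
    per = per_label_metrics(counts, scores, labels)
    out = {
        "micro_precision": float(micro_p),
        "micro_recall": float(micro_r),
        "micro_f1": float(micro_f1),
        "macro_precision": float(per["precision"].mean()),
        "macro_recall": float(per["recall"].mean()),
        "macro_f1": float(per["f1"].mean()),
    }
    if scores is not None and labels is not None:
        out["micro_auc"] = auc_score(np.asarray(scores).ravel(),
                                     np.asarray(labels).ravel())
        out["macro_auc"] = float(np.nanmean(per["auc"]))
    return out


def first_access_accuracy(F_windows: np.ndarray, Y: np.ndarray,
                          Y_hat: np.ndarray, facility: int) -> float:
    """Recall on first-access windows for one facility column (0-based).

    The subset holds test windows whose 52-week facility column is all
    zero yet whose forecast label is positive — patients visiting the
    facility for the first time.  NaN when the subset is empty.
    """
    F_windows = np.asarray(F_windows)
    never_visited = (F_windows[:, :, facility] == 0).all(axis=1)
    subset = never_visited & (np.asarray(Y)[:, facility] == 1)
    if not subset.any():
        return float("nan")
    return float(np.asarray(Y_hat)[subset, facility].mean())


def attendance_lower_bound(Y_hat: np.ndarray, Y: np.ndarray,
                           n_top: int = 10) -> dict[str, np.ndarray]:
    """Per top facility: predicted-positive count, actual positive count
    and their ratio (a conservative attendance estimate)."""
    Y_hat, Y = np.asarray(Y_hat), np.asarray(Y)
    predicted = Y_hat[:, :n_top].sum(axis=0).astype(int)
    actual = Y[:, :n_top].sum(axis=0).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(actual > 0, predicted / np.maximum(actual, 1),
                         np.nan)
    return {"predicted": predicted, "actual": actual, "ratio": ratio}


@dataclass
class MetricsReport:
    """Full evaluation of one run's test-set predictions."""

    mean_hamming: float
    exact_accuracy: float
    top10_exact_accuracy: float
    per_label: dict[str, np.ndarray]
    overall: dict[str, float]
    lower_bound: dict[str, np.ndarray]
    first_access: np.ndarray | None = None

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return [None if (isinstance(x, float) and np.isnan(x))
                        else (x.item() if hasattr(x, "item") else x)
                        for x in v.tolist()]
            return v
        return {
            "mean_hamming": self.mean_hamming,
            "exact_accuracy": self.exact_accuracy,
            "top10_exact_accuracy": self.top10_exact_accuracy,
            "per_label": {k: conv(v) for k, v in self.per_label.items()},
            "overall": dict(self.overall),
            "lower_bound": {k: conv(v) for k, v in self.lower_bound.items()},
            "first_access": conv(self.first_access)
            if self.first_access is not None else None,
        }


def evaluate_predictions(Y: np.ndarray, Y_hat: np.ndarray,
                         scores: np.ndarray,
                         F_windows: np.ndarray | None = None,
                         n_top: int = 10) -> MetricsReport:
    """Assemble the complete metrics report for one test set."""
    counts = confusion_counts(Y, Y_hat)
    first_access = None
    if F_windows is not None:
        first_access = np.array([
            first_access_accuracy(F_windows, Y, Y_hat, j)
            for j in range(n_top)
        ])
    return MetricsReport(
        mean_hamming=mean_hamming_distance(Y, Y_hat),
        exact_accuracy=exact_accuracy(Y, Y_hat),
        top10_exact_accuracy=exact_accuracy(Y, Y_hat, ignore_last=True),
        per_label=per_label_metrics(counts, scores, Y),
        overall=overall_metrics(counts, scores, Y),
        lower_bound=attendance_lower_bound(Y_hat, Y, n_top),
        first_access=first_access,
    )
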