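"""Slide-level metrics and cross-fold reporting.

AUC is the area under the ROC curve, equal to the Mann-Whitney pair
statistic (ties counted one half).  NPV and PPV are computed from confusion
counts at a score threshold (default 0.5; scores at exactly the threshold
are counted as positive calls).  High-confidence subsetting keeps only
scores below ``low`` or above ``high`` (default 0.25 / 0.75) before
recomputing metrics.  Cross-fold reports give mean +/- sample standard
deviation and compare model families by a two-sided two-sample t-test on
their per-fold AUCs.

Undefined quantities (single-class labels, empty denominators) are returned
as ``None`` with the reason recorded, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score


@dataclass
class FoldMetrics:
    fold: int
    auc: float | None
    npv: float | None
    ppv: float | None
    threshold: float
    n_validation: int
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    notes: dict = field(default_factory=dict)


class UndefinedMetric(ValueError):
    pass


def auc(scores, labels) -> float:
    """ROC AUC; raises :class:`UndefinedMetric` when one class is absent."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if len(np.unique(labels)) < 2:
        raise UndefinedMetric("AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def confusion_counts(scores, labels, threshold: float = 0.5):
    """(tp, fp, tn, fn) with scores >= threshold called positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, tn, fn


def npv_ppv(scores, labels, threshold: float = 0.5):
    """(NPV, PPV, counts dict); an empty denominator yields None for that
    metric with the cause recorded under ``counts['notes']``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    tp, fp, tn, fn = confusion_counts(scores, labels, threshold)
    notes = {}
    npv = tn / (tn + fn) if (tn + fn) else None
    if npv is None:
        notes["npv"] = "undefined: no negative calls (TN + FN = 0)"
    ppv = tp / (tp + fp) if (tp + fp) else None
    if ppv is None:
        notes["ppv"] = "undefined: no positive calls (TP + FP = 0)"
    return npv, ppv, {"tp": tp, "fp": fp, "tn": tn, "fn": fn, "notes": notes}


def high_confidence_subset(scores, low: float = 0.25, high: float = 0.75):
    """Indices of confidently called slides: score < low (wild-type call)
    or score > high (mutant call)."""
    if not low < high:
        raise ValueError("low must be below high")
    scores = np.asarray(scores, dtype=float)
    return np.flatnonzero((scores < low) | (scores > high))


def fold_metrics(fold: int, scores, labels, threshold: float = 0.5) -> FoldMetrics:
    try:
        a = auc(scores, labels)
    except UndefinedMetric:
        a = None
    npv, ppv, counts = npv_ppv(scores, labels, threshold)
    return FoldMetrics(fold=fold, auc=a, npv=npv, ppv=ppv,
                       threshold=threshold, n_validation=len(np.asarray(scores)),
                       tp=counts["tp"], fp=counts["fp"],
                       tn=counts["tn"], fn=counts["fn"],
                       notes=counts["notes"])


def mean_sd(values) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1; 0 for a single value)."""
    v = np.asarray([x for x in values if x is not None], dtype=float)
    if v.size == 0:
        raise UndefinedMetric("no defined values to aggregate")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return float(v.mean()), sd


def cross_fold_report(folds: list[FoldMetrics]) -> dict:
    """Aggregate per-fold metrics into mean +/- sd per metric."""
    if len(folds) < 2:
        raise ValueError("cross-fold report needs at least two folds")
    report = {}
    for metric in ("auc", "npv", "ppv"):
        values = [getattr(f, metric) for f in folds]
        defined = [v for v in values if v is not None]
        if defined:
            m, sd = mean_sd(defined)
            report[metric] = {"mean": m, "sd": sd, "n_folds": len(defined)}
        else:
            report[metric] = {"mean": None, "sd": None, "n_folds": 0,
                              "note": "undefined in every fold"}
    return report


def compare_families(aucs_a, aucs_b):
    """Two-sided two-sample t-test on per-fold AUCs of two model families.

    Returns (t, p); a comparison of a family with itself (zero variance in
    both samples) is flagged as undefined.
    """
    a = np.asarray(list(aucs_a), dtype=float)
    b = np.asarray(list(aucs_b), dtype=float)
    if np.allclose(a, b) and a.std() < 1e-12 and b.std() < 1e-12:
        return None, None
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)
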