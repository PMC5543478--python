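"""Classification, segmentation, and clustering metrics.

Three evaluation surfaces: bag-level ROC/AUC (classification), instance-
level F-measure (segmentation: which patches are cancerous), and cluster
purity (how well discovered subtypes match the true ones).  Purity is, by
convention, measured over true-positive instances only: instances that are
genuinely positive and flagged positive by the model.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["roc_auc", "f_measure", "purity", "true_positive_mask"]


def _binary(a) -> np.ndarray:
    a = np.asarray(a)
    return a > 0


def roc_auc(scores, labels):
    """ROC curve over all thresholds and its area.

    AUC equals the Mann-Whitney pair statistic (ties counted 1/2).
    Returns ``((fpr, tpr, thresholds), auc)``; raises if only one class is
    present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.size == 0:
        raise ValueError("scores and labels must be nonempty and aligned")
    y = labels == 1
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(y, scores)
    return (fpr, tpr, thresholds), float(roc_auc_score(y, scores))


def f_measure(pred, truth) -> float:
    """Harmonic mean of precision and recall; 0 when there are no true positives."""
    pred = _binary(pred)
    truth = _binary(truth)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be nonempty and aligned")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2.0 * precision * recall / (precision + recall)


def purity(assignment, truth_subtype) -> float:
    """Fraction of instances matching their cluster's majority true subtype.

    ``sum_clusters max_class_count / total``; 1 iff every cluster is
    single-labeled.  Invariant under cluster relabeling.
    """
    assignment = np.asarray(assignment)
    truth = np.asarray(truth_subtype)
    if assignment.shape != truth.shape or assignment.size == 0:
        raise ValueError("assignment and truth must be nonempty and aligned")
    total = 0
    for c in np.unique(assignment):
        _, counts = np.unique(truth[assignment == c], return_counts=True)
        total += int(counts.max())
    return total / assignment.size


def true_positive_mask(pred_positive, truth_positive) -> np.ndarray:
    """Instances both truly positive and predicted positive (purity's domain)."""
    return _binary(pred_positive) & _binary(truth_positive)
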