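"""Decision-stump weak learners trained from weighted feature histograms.

The weak classifier is a single-feature threshold rule ("multi-decision
stump" in the sense that one stump per feature candidate is scored each
round and the best is kept).  Instead of sorting raw instances, every
feature's weight mass is binned into a weighted histogram (positive-label
and negative-label mass per bin); the stump search then scans bin edges.
This histogram form is what makes the training loop reducible: per-shard
histograms sum to the global histogram.

Bin convention: an instance with value ``x`` falls in bin ``i`` when
``edge_i < x <= edge_{i+1}``; the minimum value falls in bin 0.  A constant
feature column gets a single catch-all bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureHistogram", "Stump", "build_weighted_histograms", "train_stump", "stump_predict"]


@dataclass
class FeatureHistogram:
    """Weighted class-mass histogram of one feature column."""

    feature_index: int
    bin_edges: np.ndarray  # (n_bins + 1,), increasing
    pos_mass: np.ndarray   # per-bin sum of |w| with target label +1
    neg_mass: np.ndarray   # per-bin sum of |w| with target label -1


@dataclass
class Stump:
    """Threshold rule: predict ``polarity`` where ``x[feature] > threshold``."""

    feature_index: int
    threshold: float
    polarity: int
    weighted_error: float

    def predict(self, instances: np.ndarray) -> np.ndarray:
        x = np.asarray(instances, dtype=np.float64)
        if x.ndim != 2 or self.feature_index >= x.shape[1]:
            raise ValueError(
                f"stump on feature {self.feature_index} cannot score "
                f"{x.shape[1] if x.ndim == 2 else '?'}-dimensional instances"
            )
        out = np.where(x[:, self.feature_index] > self.threshold, self.polarity, -self.polarity)
        return out.astype(np.float64)


def feature_edges(lo: float, hi: float, n_bins: int) -> np.ndarray:
    """Bin edges spanning [lo, hi]; a degenerate range gets one catch-all bin."""
    if lo == hi:
        return np.array([lo - 0.5, lo + 0.5])
    return np.linspace(lo, hi, n_bins + 1)


def bin_indices(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, values, side="left") - 1
    return np.clip(idx, 0, len(edges) - 2)


def histogram_masses(values, weights, target_labels, edges):
    """Per-bin (pos_mass, neg_mass) of one feature column; additive over shards."""
    n_bins = len(edges) - 1
    b = bin_indices(np.asarray(values, dtype=np.float64), edges)
    w = np.asarray(weights, dtype=np.float64)
    y = np.asarray(target_labels)
    pos = np.bincount(b, weights=w * (y == 1), minlength=n_bins)
    neg = np.bincount(b, weights=w * (y == -1), minlength=n_bins)
    return pos, neg


def build_weighted_histograms(instances, weights, target_labels, n_bins: int):
    """One :class:`FeatureHistogram` per feature column.

    ``weights`` are the nonnegative boosting weights |w_ij^k|; ``target_labels``
    are the +/-1 training labels of the current cluster's training set.
    """
    x = np.asarray(instances, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    y = np.asarray(target_labels)
    if x.ndim != 2:
        raise ValueError("instances must be a 2-D feature matrix")
    if w.shape != (x.shape[0],) or y.shape != (x.shape[0],):
        raise ValueError("need one weight and one target label per instance row")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(w > 0):
        raise ValueError("all-zero weights: nothing to learn this round")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not np.all(np.isin(y, (-1, 1))):
        raise ValueError("target labels must be -1 or +1")
    hists = []
    for d in range(x.shape[1]):
        col = x[:, d]
        edges = feature_edges(col.min(), col.max(), n_bins)
        pos, neg = histogram_masses(col, w, y, edges)
        hists.append(FeatureHistogram(d, edges, pos, neg))
    return hists


def train_stump(histograms) -> Stump:
    """Best stump over all features x bin-edge thresholds x both polarities.

    Minimizes the normalized misclassified weight mass; ties break to the
    lowest feature index, then the lowest threshold, then polarity +1, so
    the result is deterministic across platforms and shardings.
    """
    if not histograms:
        raise ValueError("train_stump: no histograms")
    total = sum(float(h.pos_mass.sum() + h.neg_mass.sum()) for h in histograms) / len(histograms)
    if total <= 0:
        raise ValueError("train_stump: histograms carry no weight mass")
    best_err = np.inf
    best = None
    for h in histograms:
        pos_total = float(h.pos_mass.sum())
        neg_total = float(h.neg_mass.sum())
        # cum_*[i] = mass strictly left of edge i (bins 0..i-1)
        cum_pos = np.concatenate(([0.0], np.cumsum(h.pos_mass)))
        cum_neg = np.concatenate(([0.0], np.cumsum(h.neg_mass)))
        # threshold at edge i, polarity +1: wrong on positives left, negatives right
        err_plus = cum_pos + (neg_total - cum_neg)
        err_minus = (pos_total - cum_pos) + cum_neg
        for i, edge in enumerate(h.bin_edges):
            for polarity, err in ((1, err_plus[i]), (-1, err_minus[i])):
                if err < best_err:
                    best_err = err
                    best = Stump(h.feature_index, float(edge), polarity, 0.0)
    assert best is not None
    best.weighted_error = float(best_err / total)
    return best


def stump_predict(stump: Stump, instances) -> np.ndarray:
    """+/-1 prediction per instance row (see :class:`Stump`)."""
    return stump.predict(np.asarray(instances, dtype=np.float64))
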