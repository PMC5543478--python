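"""Boosted MIL training: plain, clustered, and max-margin cluster competition.

Three training modes share one engine:

``mil``
    One classifier (K = 1); every instance of a positive bag is a positive
    training example.
``mcil``
    K latent subtypes initialized by K-means on the positive instances and
    held fixed; cluster k trains on its own positives against the negative
    bags' instances only.
``pmil``
    Max-margin cluster competition: cluster k trains against the negative
    bags *and* the other clusters' positive instances, and after every
    boosting round each positive instance moves to the cluster whose
    strong classifier scores it highest.

Each round t, for each cluster k: recompute bag probabilities and the
gradient-derived weights |w_ij^k|, build weighted per-feature histograms
over cluster k's training set, pick the minimum-error stump, choose its
coefficient alpha by a branch line search on the full bag-level loss
L(h^k + alpha * h_t^k), and append (alpha, stump) to the strong classifier
h^k.  Because alpha = 0 is always a candidate, the recorded loss never
increases.

All dataset-wide quantities (feature ranges, histograms, candidate-alpha
losses) are reductions of per-bag summaries, combined in global bag order
(see :mod:`milboost.parallel`); this is what makes a sharded run reproduce
the serial run exactly.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .core import (
    P_EPS,
    Bag,
    SoftmaxParams,
    bag_probability,
    instance_weight_matrix,
    sigmoid,
)
from .parallel import partition_bags, reduce_partials
from .weak import FeatureHistogram, feature_edges, histogram_masses, train_stump

__all__ = [
    "TrainConfig",
    "ClusterAssignment",
    "StrongClassifier",
    "MILModel",
    "init_clusters",
    "cluster_training_labels",
    "line_search_alpha",
    "fit",
    "reassign_clusters",
    "predict_bag",
    "predict_instances",
]

logger = logging.getLogger("milboost")

_MODES = ("mil", "mcil", "pmil")


@dataclass
class TrainConfig:
    """Training configuration; defaults follow standard practice for this model
    family (K = 5 subtypes, alpha searched on [0, 1] to 1e-5 with 100 branches).
    """

    mode: str = "pmil"
    K: int = 5
    T: int = 50
    r: float = 20.0
    search_interval: tuple = (0.0, 1.0)
    epsilon: float = 1e-5
    B: int = 100
    n_bins: int = 64
    seed: int = 0
    workers: int = 1
    class_balance: bool = False

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mode == "mil":
            self.K = 1  # plain MIL has no latent subtypes
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.r < 1:
            raise ValueError("GM exponent r must be >= 1")
        left, right = self.search_interval
        if not left < right:
            raise ValueError("search interval must satisfy left < right")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.B < 2:
            raise ValueError("need at least 2 search branches")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


@dataclass
class ClusterAssignment:
    """Latent subtype index in {1..K} for every instance of every positive bag."""

    labels: dict  # bag_id -> (m,) int array

    def copy(self) -> "ClusterAssignment":
        return ClusterAssignment({b: a.copy() for b, a in self.labels.items()})


@dataclass
class StrongClassifier:
    """Additive ensemble ``score(x) = sum_t alpha_t * stump_t(x)`` for one cluster."""

    cluster_index: int
    terms: list = field(default_factory=list)  # [(alpha, Stump), ...]

    def score(self, instances: np.ndarray) -> np.ndarray:
        x = np.asarray(instances, dtype=np.float64)
        s = np.zeros(x.shape[0], dtype=np.float64)
        for alpha, stump in self.terms:
            s += alpha * stump.predict(x)
        return s


@dataclass
class MILModel:
    """K strong classifiers plus the soft-max exponent and training metadata.

    The bag-level rule is ``H(x_i) = max_k max_j h^k(x_ij)``: a bag is
    called positive iff some instance scores positive under some cluster.
    """

    mode: str
    K: int
    r: float
    D: int
    classifiers: list
    training_log: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    assignment: ClusterAssignment | None = None

    def instance_scores(self, instances) -> np.ndarray:
        x = np.asarray(instances, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.D:
            raise ValueError(f"model expects {self.D}-dimensional instances")
        return np.column_stack([c.score(x) for c in self.classifiers])


def _validate_dataset(dataset) -> int:
    if not dataset:
        raise ValueError("empty dataset")
    labels = {bag.label for bag in dataset}
    if labels != {-1, 1}:
        raise ValueError("dataset must contain at least one positive and one negative bag")
    dims = {bag.n_features for bag in dataset}
    if len(dims) != 1:
        raise ValueError(f"inconsistent feature dimensions across bags: {sorted(dims)}")
    return dims.pop()


def init_clusters(dataset, K: int, seed: int) -> ClusterAssignment:
    """K-means (Lloyd's) partition of all positive-bag instances into K clusters.

    Deterministic given ``seed``; cluster indices are 1-based.  K = 1 assigns
    every positive-bag instance to cluster 1.
    """
    pos_bags = [bag for bag in dataset if bag.label == 1]
    blocks = [bag.instances for bag in pos_bags]
    n_total = sum(b.shape[0] for b in blocks)
    if K > n_total:
        raise ValueError(f"K={K} exceeds the {n_total} positive-bag instances")
    if K == 1:
        return ClusterAssignment({bag.bag_id: np.ones(bag.n_instances, dtype=np.int64)
                                  for bag in pos_bags})
    x = np.concatenate(blocks, axis=0)
    km = KMeans(n_clusters=K, n_init=10, random_state=int(seed) % (2**31))
    flat = km.fit_predict(x).astype(np.int64) + 1
    out, start = {}, 0
    for bag in pos_bags:
        out[bag.bag_id] = flat[start:start + bag.n_instances]
        start += bag.n_instances
    return ClusterAssignment(out)


def _bag_training_labels(label: int, assign, k: int, mode: str, m: int):
    """(labels, include) for one bag in cluster k's training set.

    pmil: every instance participates; other clusters' positives count as
    negatives.  mil/mcil: other clusters' positive-bag instances are
    excluded; negatives come from negative bags only.
    """
    if label == -1:
        labels = -np.ones(m, dtype=np.int64)
        return labels, np.ones(m, dtype=bool)
    labels = np.where(assign == k, 1, -1).astype(np.int64)
    if mode == "pmil":
        include = np.ones(assign.shape[0], dtype=bool)
    else:
        include = assign == k
    return labels, include


def cluster_training_labels(assignment: ClusterAssignment, k: int, bags, mode: str):
    """Training labels (+/-1) and inclusion mask for cluster k, over all bags.

    Returns arrays concatenated in dataset order, one entry per instance.
    Excluded instances (other clusters' positives under mil/mcil) carry
    ``include = False``; their label entry is -1 but unused.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    K = max((int(a.max()) for a in assignment.labels.values()), default=1)
    if not 1 <= k <= max(K, 1):
        raise ValueError(f"cluster index {k} outside 1..{K}")
    all_labels, all_include = [], []
    for bag in bags:
        assign = assignment.labels.get(bag.bag_id)
        if bag.label == 1 and assign is None:
            raise ValueError(f"positive bag {bag.bag_id!r} missing from assignment")
        if bag.label == -1:
            assign = np.zeros(bag.n_instances, dtype=np.int64)
        labels, include = _bag_training_labels(bag.label, assign, k, mode, bag.n_instances)
        all_labels.append(labels)
        all_include.append(include)
    return np.concatenate(all_labels), np.concatenate(all_include)


def _branch_search(profile_vec, interval, B: int, epsilon: float):
    """Iterative branch search for the minimizer of a 1-D loss profile.

    Evaluates B+1 evenly spaced points, keeps the best, recurses on the two
    subintervals adjacent to it until the interval width is <= epsilon.
    0 is always evaluated when it lies inside the interval, so the returned
    loss never exceeds the loss at alpha = 0.  Returns (alpha, loss).
    """
    left, right = float(interval[0]), float(interval[1])
    if not left < right:
        raise ValueError("search interval must satisfy left < right")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if B < 2:
        raise ValueError("need at least 2 search branches")
    best_a, best_l = None, np.inf
    if left <= 0.0 <= right:
        best_a, best_l = 0.0, float(np.asarray(profile_vec(np.array([0.0])))[0])
    while True:
        grid = np.linspace(left, right, B + 1)
        losses = np.asarray(profile_vec(grid), dtype=np.float64)
        i = int(np.argmin(losses))
        if losses[i] < best_l:
            best_a, best_l = float(grid[i]), float(losses[i])
        if right - left <= epsilon:
            break
        new_left, new_right = float(grid[max(i - 1, 0)]), float(grid[min(i + 1, B)])
        if (new_left, new_right) == (left, right):  # B=2 middle pick cannot shrink
            break
        left, right = new_left, new_right
    return best_a, best_l


def line_search_alpha(loss_profile, interval=(0.0, 1.0), B: int = 100,
                      epsilon: float = 1e-5) -> float:
    """Branch line search for ``argmin_alpha loss_profile(alpha)`` on ``interval``."""
    def vec(grid):
        return np.array([loss_profile(float(a)) for a in np.asarray(grid).ravel()])

    alpha, _ = _branch_search(vec, interval, B, epsilon)
    return alpha


class _BagState:
    """Mutable per-bag training state (scores live with the bag's shard)."""

    __slots__ = ("index", "bag", "X", "m", "wi", "scores", "assign",
                 "wk", "tlab", "g", "fixed")

    def __init__(self, index, bag, wi, K):
        self.index = index
        self.bag = bag
        self.X = bag.instances
        self.m = bag.n_instances
        self.wi = wi
        self.scores = np.zeros((self.m, K), dtype=np.float64)
        self.assign = None  # (m,) cluster indices, positive bags only


def _train(dataset, config: TrainConfig, workers: int) -> MILModel:
    dataset = list(dataset)
    D = _validate_dataset(dataset)
    K, T, r, mode = config.K, config.T, float(config.r), config.mode
    params = SoftmaxParams(r)

    n_pos = sum(1 for b in dataset if b.label == 1)
    n_neg = len(dataset) - n_pos
    states = []
    for i, bag in enumerate(dataset):
        wi = float(bag.prior_weight)
        if config.class_balance:
            wi *= len(dataset) / (2.0 * (n_pos if bag.label == 1 else n_neg))
        states.append(_BagState(i, bag, wi, K))

    assignment = init_clusters(dataset, K, config.seed)
    for st in states:
        if st.bag.label == 1:
            st.assign = assignment.labels[st.bag.bag_id].copy()

    shards = partition_bags(dataset, workers, config.seed)
    shard_idx = [sh.indices for sh in shards]
    executor = ThreadPoolExecutor(max_workers=workers) if workers > 1 else None

    def _map(fn):
        """Apply fn to every bag state; results in global bag order."""
        def run(idxs):
            return [(i, fn(states[i])) for i in idxs]

        if executor is None:
            pairs = run(range(len(states)))
        else:
            futures = [executor.submit(run, idxs) for idxs in shard_idx]
            pairs = [p for f in futures for p in f.result()]
            pairs.sort(key=lambda t: t[0])
        return [p for _, p in pairs]

    def _bag_loss(st):
        p_i, _ = bag_probability(st.scores, params)
        p_i = min(max(p_i, P_EPS), 1.0 - P_EPS)
        if st.bag.label == 1:
            return -st.wi * np.log(p_i)
        return -st.wi * np.log(1.0 - p_i)

    classifiers = [StrongClassifier(k) for k in range(1, K + 1)]
    try:
        loss = float(reduce_partials(_map(_bag_loss)))
        training_log = [{"round": 0, "cluster": 0, "loss": loss}]

        for t in range(1, T + 1):
            any_useful = False
            for k in range(1, K + 1):
                # --- local pass: gradients, training set, feature ranges ---
                def pass_weights(st, k=k):
                    p_i, p_mat = bag_probability(st.scores, params)
                    w = instance_weight_matrix(st.bag.label, st.wi, p_i, p_mat, params)
                    labels, include = _bag_training_labels(st.bag.label, st.assign, k, mode, st.m)
                    st.wk = np.abs(w[:, k - 1]) * include
                    st.tlab = labels
                    if include.any():
                        xin = st.X[include]
                        mn, mx = xin.min(axis=0), xin.max(axis=0)
                    else:
                        mn = np.full(D, np.inf)
                        mx = np.full(D, -np.inf)
                    n_members = int(np.count_nonzero(include & (labels == 1)))
                    return mn, mx, float(st.wk.sum()), n_members

                parts = _map(pass_weights)
                mn = parts[0][0].copy()
                mx = parts[0][1].copy()
                for p in parts[1:]:
                    np.minimum(mn, p[0], out=mn)
                    np.maximum(mx, p[1], out=mx)
                mass = float(reduce_partials([p[2] for p in parts]))
                n_members = int(reduce_partials([p[3] for p in parts]))
                if n_members == 0 or mass <= 0.0:
                    logger.warning("round %d cluster %d: empty training set, skipped", t, k)
                    training_log.append({"round": t, "cluster": k, "skipped": True,
                                         "loss": loss})
                    continue

                # --- merged reduction: per-feature weighted histograms ---
                edges = [feature_edges(float(mn[d]), float(mx[d]), config.n_bins)
                         for d in range(D)]

                def pass_hist(st):
                    return [histogram_masses(st.X[:, d], st.wk, st.tlab, edges[d])
                            for d in range(D)]

                masses = reduce_partials(_map(pass_hist))
                hists = [FeatureHistogram(d, edges[d], masses[d][0], masses[d][1])
                         for d in range(D)]
                stump = train_stump(hists)

                # --- broadcast stump; cache predictions and fixed GM terms ---
                def pass_cache(st, k=k):
                    st.g = stump.predict(st.X)
                    p_all = np.clip(sigmoid(2.0 * st.scores), P_EPS, 1.0 - P_EPS)
                    other = np.delete(p_all, k - 1, axis=1)
                    st.fixed = float(np.sum(other**r))
                    return 0.0

                _map(pass_cache)

                # --- merged reduction: candidate-alpha loss vectors ---
                def profile(grid, k=k):
                    grid = np.asarray(grid, dtype=np.float64)

                    def bag_losses(st):
                        s_new = st.scores[:, k - 1][:, None] + grid[None, :] * st.g[:, None]
                        p = np.clip(sigmoid(2.0 * s_new), P_EPS, 1.0 - P_EPS)
                        tot = st.fixed + np.sum(p**r, axis=0)
                        p_i = np.clip((tot / (st.m * K)) ** (1.0 / r), P_EPS, 1.0 - P_EPS)
                        if st.bag.label == 1:
                            return -st.wi * np.log(p_i)
                        return -st.wi * np.log(1.0 - p_i)

                    return reduce_partials(_map(bag_losses))

                alpha, loss = _branch_search(profile, config.search_interval,
                                             config.B, config.epsilon)
                classifiers[k - 1].terms.append((alpha, stump))

                def pass_update(st, k=k, alpha=alpha):
                    st.scores[:, k - 1] += alpha * st.g
                    return 0.0

                _map(pass_update)

                if stump.weighted_error < 0.5 - 1e-12:
                    any_useful = True
                training_log.append({
                    "round": t, "cluster": k, "feature": stump.feature_index,
                    "threshold": stump.threshold, "polarity": stump.polarity,
                    "weighted_error": stump.weighted_error, "alpha": alpha,
                    "loss": loss,
                })
                logger.info("t=%d k=%d feature=%d err=%.4f alpha=%.6f loss=%.6f",
                            t, k, stump.feature_index, stump.weighted_error, alpha, loss)

            if not any_useful:
                logger.warning("early stop at round %d: no weak learner beats chance", t)
                break

            if mode == "pmil":
                # cluster competition: each positive instance moves to the
                # cluster whose strong classifier scores it highest
                def pass_reassign(st):
                    if st.bag.label == 1:
                        st.assign = np.argmax(st.scores, axis=1).astype(np.int64) + 1
                    return 0.0

                _map(pass_reassign)
    finally:
        if executor is not None:
            executor.shutdown(wait=False)

    final = ClusterAssignment({st.bag.bag_id: st.assign.copy()
                               for st in states if st.bag.label == 1})
    cfg = {f: getattr(config, f) for f in
           ("mode", "K", "T", "r", "search_interval", "epsilon", "B",
            "n_bins", "seed", "workers", "class_balance")}
    cfg["search_interval"] = list(cfg["search_interval"])
    return MILModel(mode=mode, K=K, r=r, D=D, classifiers=classifiers,
                    training_log=training_log, config=cfg, assignment=final)


def fit(dataset, config: TrainConfig) -> MILModel:
    """Serial training (see the module docstring for the per-round procedure).

    ``T = 0`` returns a null model that scores every instance 0 and every
    bag probability 0.5.
    """
    return _train(dataset, config, workers=1)


def reassign_clusters(model: MILModel, dataset, current: ClusterAssignment) -> ClusterAssignment:
    """Move every positive-bag instance to ``argmax_k p_ij^k`` (ties: lowest k).

    Negative-bag instances are untouched; with K = 1 this is the identity.
    The instance probability is monotone in the score, so the argmax is
    taken directly over the K strong-classifier scores.
    """
    out = {}
    for bag in dataset:
        if bag.label != 1:
            continue
        scores = model.instance_scores(bag.instances)
        out[bag.bag_id] = np.argmax(scores, axis=1).astype(np.int64) + 1
    return ClusterAssignment(out)


def predict_bag(model: MILModel, bag: Bag):
    """Bag score ``max_k max_j h^k(x_ij)`` and label (+1 iff score > 0)."""
    scores = model.instance_scores(bag.instances)
    score = float(scores.max())
    return score, (1 if score > 0 else -1)


def predict_instances(model: MILModel, bag: Bag):
    """Per-instance cluster scores, best cluster (1-based), and positive flag.

    Returns ``(scores, best_cluster, positive)`` where ``scores`` is
    (m, K), ``best_cluster`` is the argmax cluster (ties to the lowest
    index), and ``positive`` marks instances with ``max_k score > 0``.
    """
    scores = model.instance_scores(bag.instances)
    best = np.argmax(scores, axis=1).astype(np.int64) + 1
    positive = scores.max(axis=1) > 0
    return scores, best, positive
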