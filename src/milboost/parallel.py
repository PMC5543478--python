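"""Bag-unit data sharding and deterministic merged reductions.

Training is data-parallel in the bags: each worker owns a disjoint set of
whole bags (an instance never leaves its bag's shard), computes shard-local
additive summaries (per-feature weighted histograms; per-candidate line
search losses), and a coordinator combines the partials and broadcasts the
globally selected stump and step size.

Reductions always combine per-bag partials in the global dataset order,
regardless of which worker produced them.  Floating-point addition is not
associative, so a fixed combination order is what makes a parallel run
reproduce the serial run bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Shard", "partition_bags", "reduce_partials", "parallel_fit"]


@dataclass
class Shard:
    """One worker's disjoint subset of the dataset (whole bags only)."""

    worker_index: int
    bags: list
    indices: list = field(default_factory=list)  # global dataset positions, ascending


def partition_bags(dataset, workers: int, seed: int = 0):
    """Split bags into ``workers`` disjoint shards, balanced by instance count.

    Bags are considered in a seed-determined order and greedily assigned to
    the least-loaded shard, so shard sizes (in instances) differ by at most
    the largest single bag.  Within a shard, bags keep their global order.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    loads = np.zeros(workers)
    members = [[] for _ in range(workers)]
    for idx in order:
        w = int(np.argmin(loads))  # ties -> lowest worker index
        members[w].append(int(idx))
        loads[w] += dataset[idx].n_instances
    shards = []
    for w in range(workers):
        idxs = sorted(members[w])
        shards.append(Shard(w, [dataset[i] for i in idxs], idxs))
    return shards


def _add(a, b):
    if isinstance(a, np.ndarray):
        b = np.asarray(b)
        if a.shape != b.shape:
            raise ValueError(f"reduce_partials: shape mismatch {a.shape} vs {b.shape}")
        return a + b
    if isinstance(a, (tuple, list)):
        if not isinstance(b, (tuple, list)) or len(a) != len(b):
            raise ValueError("reduce_partials: structure mismatch")
        out = [_add(x, y) for x, y in zip(a, b)]
        return type(a)(out) if isinstance(a, tuple) else out
    return a + b


def reduce_partials(partials):
    """Elementwise sum of additive summaries, folded left in the given order.

    Accepts arrays, numbers, or (nested) tuples/lists of them.  The fold
    order is fixed by the caller (global bag order in training), never by
    worker completion order.
    """
    partials = list(partials)
    if not partials:
        raise ValueError("reduce_partials: nothing to reduce")
    acc = partials[0]
    for p in partials[1:]:
        acc = _add(acc, p)
    return acc


def parallel_fit(dataset, config):
    """Train with ``config.workers`` workers; equal to serial :func:`~milboost.boosting.fit`.

    The worker pool changes only who computes each bag's partials; every
    reduction combines the same per-bag summaries in the same order, so the
    resulting model (stump sequence, step sizes, logs) is identical to a
    serial run with the same configuration.
    """
    from .boosting import _train

    return _train(dataset, config, workers=config.workers)
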