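"""Synthetic bag-structured datasets with known instance labels and subtypes.

Emulates the structure of weakly-labeled histopathology data: a bag is a
cropped piece, instances are patch feature vectors.  Negative instances
are standard-normal noise at the origin; positive instances of subtype s
are unit-covariance Gaussians whose mean lies ``separation`` standard
deviations along the s-th coordinate axis.  Every positive bag mixes
``ceil(pos_fraction * m)`` positive instances with negative filler, so the
MIL bag-labeling rule (positive iff at least one positive instance) holds
by construction; negative bags contain no positive instance.

Generation is keyed by bag identity (seed, bag role, bag number), not by
position in the dataset, so bag contents are stable under reordering or
resizing of the other class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Bag

__all__ = ["SynthConfig", "GroundTruth", "generate", "default_benchmark", "overlap_benchmark"]

#: benchmark seed (fixed date-like constant)
BENCHMARK_SEED = 20110501


@dataclass
class SynthConfig:
    """Generator settings.

    ``separation`` is the distance between a subtype mean and the origin in
    units of the (unit) component standard deviation; 6 gives essentially
    disjoint subtypes, 2 gives heavily overlapping ones.
    """

    n_pos_bags: int = 40
    n_neg_bags: int = 40
    m: int = 30
    D: int = 10
    K_true: int = 3
    separation: float = 6.0
    pos_fraction: float = 0.3
    subtypes_per_bag: int = 1
    seed: int = BENCHMARK_SEED

    def __post_init__(self) -> None:
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        if self.K_true > self.D:
            raise ValueError("need K_true <= D (subtype means are coordinate axes)")
        if self.n_pos_bags < 1 or self.n_neg_bags < 1:
            raise ValueError("need at least one bag of each class")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0.0 < self.pos_fraction <= 1.0:
            raise ValueError("pos_fraction must lie in (0, 1]")
        if not 1 <= self.subtypes_per_bag <= self.K_true:
            raise ValueError("subtypes_per_bag must lie in 1..K_true")


@dataclass
class GroundTruth:
    """Per-instance truth: positive flag and subtype index (0 for negative)."""

    positive: dict  # bag_id -> (m,) bool array
    subtype: dict   # bag_id -> (m,) int array, 0 where negative


def _positive_bag(config: SynthConfig, index: int):
    rng = np.random.default_rng([config.seed, 1, index])
    n_pos = math.ceil(config.pos_fraction * config.m)
    available = rng.choice(config.K_true, size=config.subtypes_per_bag, replace=False) + 1
    subtypes = rng.choice(available, size=n_pos, replace=True)
    x = rng.standard_normal((config.m, config.D))
    rows = rng.permutation(config.m)[:n_pos]
    positive = np.zeros(config.m, dtype=bool)
    subtype = np.zeros(config.m, dtype=np.int64)
    for row, s in zip(rows, subtypes):
        x[row, s - 1] += config.separation
        positive[row] = True
        subtype[row] = s
    return x, positive, subtype


def generate(config: SynthConfig):
    """Draw a dataset and its ground truth; deterministic given ``config.seed``."""
    bags, positive, subtype = [], {}, {}
    for b in range(config.n_pos_bags):
        bag_id = f"pos{b:04d}"
        x, flags, subs = _positive_bag(config, b)
        assert flags.any(), "MIL assumption: every positive bag has a positive instance"
        bags.append(Bag(bag_id, 1, x))
        positive[bag_id] = flags
        subtype[bag_id] = subs
    for b in range(config.n_neg_bags):
        bag_id = f"neg{b:04d}"
        rng = np.random.default_rng([config.seed, 0, b])
        bags.append(Bag(bag_id, -1, rng.standard_normal((config.m, config.D))))
        positive[bag_id] = np.zeros(config.m, dtype=bool)
        subtype[bag_id] = np.zeros(config.m, dtype=np.int64)
    return bags, GroundTruth(positive, subtype)


def default_benchmark(seed: int = BENCHMARK_SEED):
    """The separable benchmark: 40+40 bags, m=30, D=10, 3 subtypes at separation 6."""
    return generate(SynthConfig(seed=seed))


def overlap_benchmark(seed: int = BENCHMARK_SEED):
    """The confusable-subtype variant (separation 2) used to compare training modes."""
    return generate(SynthConfig(separation=2.0, seed=seed))
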