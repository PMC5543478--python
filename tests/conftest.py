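import logging

import numpy as np
import pytest

from milboost.core import Bag

logging.getLogger("milboost").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)


def random_problem(rng, n_bags=3, max_m=5, max_k=3, D=4):
    """A small random bag problem with random strong-classifier scores."""
    K = int(rng.integers(1, max_k + 1))
    bags, scores = [], []
    labels = [1, -1] + [int(rng.choice([-1, 1])) for _ in range(n_bags - 2)]
    for i, y in enumerate(labels):
        m = int(rng.integers(1, max_m + 1))
        bags.append(Bag(f"b{i}", y, rng.standard_normal((m, D)),
                        prior_weight=float(rng.uniform(0.5, 2.0))))
        scores.append(rng.standard_normal((m, K)) * 1.5)
    return bags, scores, K


@pytest.fixture
def tiny_dataset(rng):
    """Two positive + two negative bags, 1-D separable features."""
    pos = [Bag(f"p{i}", 1, np.array([[3.0 + i], [0.1 * i], [-0.2]])) for i in range(2)]
    neg = [Bag(f"n{i}", -1, np.array([[-1.0 - i], [0.2], [-0.5 * i]])) for i in range(2)]
    return pos + neg
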