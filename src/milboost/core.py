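"""Bag-level probabilities, loss, and gradient-derived instance weights.

Multiple instance learning (MIL) supervises at the bag level: a bag of
instances is positive iff at least one instance is positive.  Boosting a
bag-level negative log-likelihood requires a differentiable surrogate for
the max over instances; here that surrogate is the generalized-mean (GM)
soft-max

    g_r(v_1..v_m) = ((1/m) * sum_l v_l**r) ** (1/r),        r >= 1,

which interpolates between the arithmetic mean (r=1) and the hard max
(r -> inf).  Instance probabilities are ``p = sigma(2 h)`` for additive
classifier scores ``h``; the bag probability is one joint GM over all
m x K instance-cluster probabilities, and the per-instance boosting
weights are the (negated) chain-rule derivatives of the loss with respect
to the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "P_EPS",
    "Bag",
    "SoftmaxParams",
    "sigmoid",
    "gm_softmax",
    "gm_softmax_grad",
    "bag_probability",
    "total_loss",
    "instance_weights",
    "instance_weight_matrix",
]

#: probabilities are clamped into [P_EPS, 1 - P_EPS] before logs; the
#: negative log-likelihood diverges at 0 and 1.
P_EPS = 1e-12


@dataclass
class SoftmaxParams:
    """GM soft-max exponent ``r`` (>= 1); larger values sharpen toward max."""

    r: float = 20.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.r) or self.r < 1.0:
            raise ValueError(f"GM exponent r must be >= 1, got {self.r!r}")


@dataclass
class Bag:
    """One labeled group of instances.

    Parameters
    ----------
    bag_id : opaque identifier.
    label : bag label, exactly -1 or +1.
    instances : (m, D) float array, one feature row per instance.
    prior_weight : nonnegative multiplier of this bag's loss term.
    """

    bag_id: str
    label: int
    instances: np.ndarray
    prior_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in (-1, 1):
            raise ValueError(f"bag {self.bag_id!r}: label must be -1 or +1, got {self.label!r}")
        self.instances = np.asarray(self.instances, dtype=np.float64)
        if self.instances.ndim != 2 or self.instances.shape[0] < 1:
            raise ValueError(f"bag {self.bag_id!r}: instances must be a nonempty 2-D array")
        if not np.all(np.isfinite(self.instances)):
            raise ValueError(f"bag {self.bag_id!r}: non-finite feature value")
        if not (np.isfinite(self.prior_weight) and self.prior_weight >= 0):
            raise ValueError(f"bag {self.bag_id!r}: prior_weight must be >= 0")

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]

    @property
    def n_features(self) -> int:
        return self.instances.shape[1]


def sigmoid(v):
    """Logistic function ``1 / (1 + exp(-v))``, strictly in (0, 1)."""
    v = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("sigmoid: non-finite input")
    out = np.empty_like(v)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ev = np.exp(v[~pos])
    out[~pos] = ev / (1.0 + ev)
    return out if out.ndim else float(out)


def _check_probs(values) -> np.ndarray:
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("GM soft-max of an empty collection is undefined")
    if not np.all((v > 0.0) & (v < 1.0)):
        raise ValueError("GM soft-max inputs must lie strictly in (0, 1)")
    return v


def gm_softmax(values, params: SoftmaxParams) -> float:
    """Generalized mean of probabilities; lies in [min(values), max(values)].

    Computed as ``M * mean((v/M)**r)**(1/r)`` with ``M = max(v)`` so that
    large exponents cannot underflow every term.
    """
    v = _check_probs(values).ravel()
    r = params.r
    m = v.max()
    return float(m * np.mean((v / m) ** r) ** (1.0 / r))


def gm_softmax_grad(values, params: SoftmaxParams) -> np.ndarray:
    """Gradient dg/dv_l of :func:`gm_softmax`; every entry is positive.

    For the degree-1 homogeneous GM the Euler identity
    ``sum_l v_l * dg/dv_l = g`` holds exactly.
    """
    v = _check_probs(values)
    shape = v.shape
    v = v.ravel()
    r = params.r
    m = v.max()
    u = v / m
    g = m * np.mean(u**r) ** (1.0 / r)
    grad = (g / m) * u ** (r - 1.0) / np.sum(u**r)
    return grad.reshape(shape)


def bag_probability(scores, params: SoftmaxParams):
    """Bag probability from an (m, K) matrix of strong-classifier scores.

    Returns ``(p_i, p_matrix)`` where ``p_matrix = sigma(2 * scores)``
    clamped away from {0, 1} and ``p_i`` is the joint GM soft-max over all
    m*K entries (the soft-max is indexed by instance and cluster together).
    """
    s = np.asarray(scores, dtype=np.float64)
    if s.size == 0:
        raise ValueError("bag_probability: empty score matrix")
    if s.ndim == 1:
        s = s[:, None]
    if s.ndim != 2:
        raise ValueError("bag_probability: scores must be an (m, K) matrix")
    p_matrix = np.clip(sigmoid(2.0 * s), P_EPS, 1.0 - P_EPS)
    p_i = gm_softmax(p_matrix, params)
    return p_i, p_matrix


def total_loss(bags, probs) -> float:
    """Weighted negative log-likelihood of the bag labels.

    ``L = -sum_i w_i [1(y_i=1) log p_i + 1(y_i=-1) log(1 - p_i)]`` with
    probabilities clamped to [P_EPS, 1-P_EPS] before the logs.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape != (len(bags),):
        raise ValueError("total_loss: need exactly one probability per bag")
    if not np.all((probs >= 0.0) & (probs <= 1.0)):
        raise ValueError("total_loss: probabilities must lie in [0, 1]")
    p = np.clip(probs, P_EPS, 1.0 - P_EPS)
    loss = 0.0
    for bag, p_i in zip(bags, p):
        if bag.label == 1:
            loss -= bag.prior_weight * np.log(p_i)
        else:
            loss -= bag.prior_weight * np.log(1.0 - p_i)
    return float(loss)


def instance_weight_matrix(label: int, prior_weight: float, p_i: float,
                           p_matrix, params: SoftmaxParams) -> np.ndarray:
    """Boosting weights ``w_ij^k = -dL/dh_ij^k`` for one bag.

    Chain rule through the clamped sigmoid and the joint GM:

    * ``dL/dp_i   = -w_i / p_i``            if y_i = +1,
      ``dL/dp_i   = +w_i / (1 - p_i)``      if y_i = -1,
    * ``dp_i/dp_ij^k = p_i * (p_ij^k)^(r-1) / sum_{j,k} (p_ij^k)^r``,
    * ``dp_ij^k/dh_ij^k = 2 p_ij^k (1 - p_ij^k)``.

    The sign of every entry equals the bag label.
    """
    p = np.asarray(p_matrix, dtype=np.float64)
    r = params.r
    m = p.max()
    u = p / m
    # p_i * p^(r-1) / sum(p^r), max-normalized so large r cannot underflow
    dpi_dp = p_i * u ** (r - 1.0) / (m * np.sum(u**r))
    dp_dh = 2.0 * p * (1.0 - p)
    if label == 1:
        dl_dpi = -prior_weight / max(p_i, P_EPS)
    else:
        dl_dpi = prior_weight / max(1.0 - p_i, P_EPS)
    return -dl_dpi * dpi_dp * dp_dh


def instance_weights(bag: Bag, p_i: float, p_matrix, params: SoftmaxParams) -> np.ndarray:
    """Per-instance, per-cluster boosting weights for ``bag`` (an m x K matrix)."""
    p = np.asarray(p_matrix, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != bag.n_instances:
        raise ValueError("instance_weights: p_matrix shape inconsistent with bag")
    return instance_weight_matrix(bag.label, bag.prior_weight, p_i, p, params)
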