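# Methods

## Model and assumptions

The package implements bag-level supervised learning under the standard MIL
assumption: a bag is positive iff at least one of its instances is positive.
Instances additionally carry a latent subtype `k ∈ {1…K}`; one additive
stump ensemble `h^k` is learned per subtype, and an instance is called
positive when `max_k h^k(x) > 0`.

The loss is the prior-weighted negative log-likelihood of the bag labels.
The bag probability uses the generalized mean (GM)

    p_i = ( (1/(mK)) Σ_{j,k} (p_ij^k)^r )^(1/r),   p_ij^k = σ(2 h^k(x_ij)),

taken *jointly* over instances and subtypes (one soft-max indexed by (j, k),
not nested means). The boosting weights are the exact chain-rule
derivatives:

    w_ij^k = −(∂L/∂p_i) · (∂p_i/∂p_ij^k) · (∂p_ij^k/∂h_ij^k),
    ∂p_i/∂p_ij^k = p_i (p_ij^k)^(r−1) / Σ_{j,k} (p_ij^k)^r,
    ∂p_ij^k/∂h_ij^k = 2 p_ij^k (1 − p_ij^k),

so `sign(w_ij^k) = y_i` always. The prior weight `w_i` multiplies the
gradient weights, since it multiplies the bag's loss term; an optional
class-balancing mode sets `w_i = n/(2 n_class)`.

Each boosting round t, for each subtype k: probabilities and weights are
recomputed (freshest-gradient policy — recomputing before each subtype's
update rather than freezing once per round; the alternative would only
stale the inner updates), weighted per-feature histograms are built over
subtype k's training set, the minimum-weighted-error stump is selected, and
α is found by branch line search on the full bag-level loss. In `pmil`
mode, after the K inner updates every positive-bag instance is reassigned
to `argmax_k p_ij^k` (equivalently `argmax_k h^k`, since σ is monotone);
negative-bag instances never move, and ties go to the lowest k. `mcil`
keeps its K-means initialization fixed for all rounds. `mil` is the K = 1
special case and is bit-identical to `mcil` at K = 1.

Negative bags contribute to every subtype's GM through their instances'
scores under all K classifiers — there is no per-subtype restriction of the
soft-max.

## The GM loss floor

The GM bounds how confident a positive bag can get. If a positive bag has
`q` truly positive instances out of `m`, and only those reach probability
≈ 1 under exactly one subtype while everything else is driven to 0, then
`p_i ≤ (q/(mK))^(1/r)` and the loss cannot fall below

    L_floor = Σ_{positive bags} w_i · ln(mK/q) / r.

On the default benchmark (40 positive bags, m = 30, K = 3, q = 9, r = 20)
this is 40·ln(10)/20 ≈ 4.61. Training reaches within half a percent of this
floor; "loss → 0" is impossible for any classifier that still rejects
negative bags. Raising r lowers the floor at the cost of max-like, more
concentrated gradients.

## Parameters

| name | default | meaning / rationale |
|------|---------|---------------------|
| `mode` | `pmil` | `mil`, `mcil`, or `pmil` (see above) |
| `K` | 5 | number of latent subtypes; the recovery tests use K = 3 to match the generator |
| `T` | 50 | boosting rounds; each adds ≤ K stumps |
| `r` | 20 | GM exponent (≥ 1): steep enough to approximate max while keeping gradient mass spread over several instances; recorded in the model file |
| `search_interval` | [0, 1] | admissible α range for the line search |
| `epsilon` | 1e−5 | line-search interval width at termination |
| `B` | 100 | line-search branches per refinement (B+1 grid points) |
| `n_bins` | 64 | histogram bins per feature; thresholds are bin edges, so this is the threshold resolution |
| `workers` | 1 | shard count for data-parallel training |

## Numerical and tie-break conventions

- Probabilities are clamped to `[1e−12, 1−1e−12]` before logs; the GM and
  its gradient are computed max-normalized (`(v/max v)^r`) so large r cannot
  underflow every term. The vectorized candidate-α path uses raw power sums,
  adequate for r up to roughly 50 on clamped probabilities.
- Stump ties break to the lowest feature index, then the lowest threshold,
  then polarity +1. Instance binning: bin i holds `edge_i < x ≤ edge_{i+1}`,
  minima fall in bin 0, constant columns get one catch-all bin.
- The line search always evaluates α = 0 when the interval contains it, so
  each update can only lower the recorded loss (monotone training, enforced
  to 1e−9 in tests).
- A subtype whose training set is empty (all its instances captured by
  competitors) is skipped for that round with a warning — clusters are
  allowed to die out, never silently re-seeded. If no subtype's best stump
  beats chance (weighted error ≥ 0.5) in a round, training stops early.
- All dataset-wide reductions (feature ranges, histograms, candidate-α
  losses) combine per-bag partials in global bag order. Floating-point
  addition is not associative, so this fixed order is what makes
  `parallel_fit` reproduce `fit` exactly for any worker count; worker
  completion order never matters. The worker pool is threads in one
  process; distribution across machines is out of scope.

## Synthetic data: what it does and does not emulate

The generator emulates the *structure* of weakly-labeled histopathology
features: bags of D-dimensional instance vectors, a minority of positive
instances per positive bag (`ceil(pos_fraction·m)`, default 9/30), subtype
identity for every positive instance, and pure-noise negative bags.
Negative instances are standard normal at the origin; subtype s sits at
distance `separation` along coordinate axis s with unit covariance. The
default benchmark uses separation 6 (essentially disjoint subtypes); the
overlap variant uses separation 2 (heavily confusable).

It does **not** emulate real patch descriptors: no correlated features, no
multi-scale structure, no spatial adjacency between instances, no label
noise, and subtype means are axis-aligned — which flatters single-feature
stumps. Passing the recovery tests therefore shows the training machinery
is correct and can recover planted structure, not that it attains any
particular accuracy on real tissue.

Generation is keyed by (seed, bag role, bag number), so a bag's contents do
not depend on how many bags of the other class exist or on dataset order.

## What the suite measures

Correctness is pinned by independent oracles: Richardson-extrapolated
finite differences for the gradient weights, exhaustive threshold
enumeration for the stump learner, a 10^6-point grid for the line search,
explicit pair counting for AUC, and hand-counted worked examples for
F-measure and purity. Structural contracts (MIL ≡ MCIL at K = 1; serial ≡
sharded) are asserted bit-exactly.

On the separable benchmark, `pmil` (K = 3, T = 50) recovers bag labels
(AUC ≥ 0.95), instance labels (F ≥ 0.85), and subtype identity
(purity ≥ 0.90) on at least 8 of 10 seeds, with purity typically 1.0 —
the cluster competition repairs an imperfect K-means initialization when
subtypes are separable. On the overlap benchmark the same competition does
not help clustering: reassignment driven by weak axis-aligned stump scores
degrades a decent K-means initialization, and the measured median purity of
`pmil` falls slightly below `mcil` (the corresponding ordering test
documents this as a failing expectation). Both cluster-aware modes beat
plain `mil` on segmentation F-measure in either regime. Purity is measured
on true-positive instances (truly positive *and* predicted positive) by
default; an `all-positives` variant is available and gives the same
ordering.

Problem sizes throughout (80 bags × 30 instances × 10 features, T ≤ 50,
10 seeds per stochastic claim) are chosen so any single check completes in
minutes on one core while leaving the stochastic claims well away from
single-seed noise.

## Known limitations

- The GM exponent interacts with bag size: for very large m·K the floor
  argument above means positive bags need many confident instances before
  p_i approaches 1; r should grow with log(mK) if near-zero loss matters.
- Thresholds are restricted to histogram bin edges; with `n_bins` below the
  number of distinct values the stump is only optimal to binning
  granularity.
- Cluster competition has no safeguard against subtype collapse beyond
  logging; on data where subtypes are not separable by single features it
  can merge or churn clusters (see the overlap findings above).
- The model file stores stumps and coefficients but not the data; purity
  and F-measure require ground-truth columns in the instance table.
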