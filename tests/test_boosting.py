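"""Training modes, K-means initialization, line search, and cluster competition."""

import itertools

import numpy as np
import pytest

from milboost.boosting import (
    ClusterAssignment,
    MILModel,
    StrongClassifier,
    TrainConfig,
    cluster_training_labels,
    fit,
    init_clusters,
    line_search_alpha,
    predict_bag,
    predict_instances,
    reassign_clusters,
)
from milboost.core import Bag, SoftmaxParams, bag_probability, sigmoid
from milboost.synthetic import default_benchmark
from milboost.weak import Stump


def blob_dataset(rng, centers, n_per=10, spread=1.0):
    """Positive bags, one per blob, plus one negative bag at the origin."""
    bags = []
    for i, c in enumerate(centers):
        x = rng.standard_normal((n_per, len(c))) * spread + np.asarray(c)
        bags.append(Bag(f"p{i}", 1, x))
    bags.append(Bag("n0", -1, rng.standard_normal((n_per, len(centers[0])))))
    return bags


def one_stump_model(K, alpha=0.7):
    """K identical single-stump classifiers: score +alpha where x[0] > 0."""
    clfs = [StrongClassifier(k + 1, [(alpha, Stump(0, 0.0, 1, 0.1))]) for k in range(K)]
    return MILModel(mode="pmil", K=K, r=20.0, D=2, classifiers=clfs)


class TestInitClusters:
    def test_k1_assigns_everything_to_cluster_one(self, tiny_dataset):
        a = init_clusters(tiny_dataset, 1, seed=0)
        assert set(a.labels) == {"p0", "p1"}
        assert all(np.all(v == 1) for v in a.labels.values())

    def test_recovers_separated_blobs(self, rng):
        centers = [[30.0, 0.0], [0.0, 30.0], [-30.0, -30.0]]
        bags = blob_dataset(rng, centers)
        a = init_clusters(bags, 3, seed=5)
        best = 0
        for perm in itertools.permutations([1, 2, 3]):
            hits = sum(np.sum(a.labels[f"p{i}"] == perm[i]) for i in range(3))
            best = max(best, hits)
        assert best == 30  # every instance matches its blob, up to relabeling

    def test_deterministic_given_seed(self, rng):
        bags = blob_dataset(rng, [[5.0, 0.0], [0.0, 5.0]])
        a1 = init_clusters(bags, 2, seed=11)
        a2 = init_clusters(bags, 2, seed=11)
        assert all(np.array_equal(a1.labels[b], a2.labels[b]) for b in a1.labels)

    def test_rejects_k_larger_than_instances(self, tiny_dataset):
        with pytest.raises(ValueError):
            init_clusters(tiny_dataset, 100, seed=0)


class TestClusterTrainingLabels:
    @pytest.fixture
    def small(self):
        pos = Bag("p", 1, np.zeros((3, 2)))
        neg = Bag("n", -1, np.zeros((2, 2)))
        assignment = ClusterAssignment({"p": np.array([1, 2, 1])})
        return [pos, neg], assignment

    def test_mil_broadcasts_bag_labels(self, tiny_dataset):
        a = init_clusters(tiny_dataset, 1, seed=0)
        labels, include = cluster_training_labels(a, 1, tiny_dataset, "mil")
        expected = np.concatenate([[b.label] * b.n_instances for b in tiny_dataset])
        assert np.array_equal(labels, expected)
        assert include.all()

    def test_pmil_other_clusters_count_as_negatives(self, small):
        bags, a = small
        labels, include = cluster_training_labels(a, 1, bags, "pmil")
        assert np.array_equal(labels, [1, -1, 1, -1, -1])
        assert include.all()

    def test_mcil_excludes_other_clusters(self, small):
        bags, a = small
        labels, include = cluster_training_labels(a, 1, bags, "mcil")
        assert np.array_equal(include, [True, False, True, True, True])
        assert np.array_equal(labels[include], [1, 1, -1, -1])

    def test_rejects_bad_cluster_index(self, small):
        bags, a = small
        with pytest.raises(ValueError):
            cluster_training_labels(a, 7, bags, "pmil")


class TestLineSearch:
    def test_quadratic_minimum(self):
        alpha = line_search_alpha(lambda a: (a - 0.3) ** 2, (0.0, 1.0), B=100, epsilon=1e-5)
        assert alpha == pytest.approx(0.3, abs=1e-5)

    def test_decreasing_profile_hits_right_boundary(self):
        alpha = line_search_alpha(lambda a: -a, (0.0, 1.0), B=100, epsilon=1e-5)
        assert alpha == pytest.approx(1.0, abs=1e-9)

    def test_never_worse_than_zero(self):
        # increasing profile: alpha = 0 is the best admissible step
        alpha = line_search_alpha(lambda a: a + 1.0, (0.0, 1.0), B=20, epsilon=1e-4)
        assert alpha == 0.0

    def test_rejects_bad_epsilon(self):
        with pytest.raises(ValueError):
            line_search_alpha(lambda a: a, (0.0, 1.0), B=10, epsilon=0.0)


class TestFit:
    def test_null_model_scores_half(self, tiny_dataset):
        model = fit(tiny_dataset, TrainConfig(mode="pmil", K=2, T=0, seed=0))
        for bag in tiny_dataset:
            score, label = predict_bag(model, bag)
            assert score == 0.0 and label == -1
            p_i, _ = bag_probability(model.instance_scores(bag.instances),
                                     SoftmaxParams(model.r))
            assert p_i == pytest.approx(0.5)

    def test_rejects_single_class_and_ragged_dims(self):
        pos_only = [Bag("a", 1, np.zeros((2, 2))), Bag("b", 1, np.zeros((2, 2)))]
        with pytest.raises(ValueError):
            fit(pos_only, TrainConfig(mode="mil", T=1))
        ragged = [Bag("a", 1, np.zeros((2, 2))), Bag("b", -1, np.zeros((2, 3)))]
        with pytest.raises(ValueError):
            fit(ragged, TrainConfig(mode="mil", T=1))

    def test_early_stop_when_no_stump_beats_chance(self):
        # identical constant features in both classes: weighted error is 0.5
        bags = [Bag("p", 1, np.zeros((2, 1))), Bag("n", -1, np.zeros((2, 1)))]
        model = fit(bags, TrainConfig(mode="mil", T=5, seed=0))
        rounds = {e["round"] for e in model.training_log}
        assert max(rounds) <= 1  # truncated after the first chance-level round

    def test_loss_approaches_gm_floor_on_separable_benchmark(self):
        """The joint GM caps a positive bag's probability at
        (n_pos/(m*K))**(1/r), so the loss cannot fall below
        n_bags * ln(m*K/n_pos) / r; training should get close to that floor
        while cutting the initial loss by an order of magnitude."""
        bags, truth = default_benchmark()
        cfg = TrainConfig(mode="pmil", K=3, T=50, r=20.0, seed=3)
        model = fit(bags, cfg)
        losses = [e["loss"] for e in model.training_log]
        n_pos_entries = 9  # ceil(0.3 * 30) positive instances per positive bag
        floor = 40 * np.log((30 * 3) / n_pos_entries) / cfg.r
        assert losses[0] == pytest.approx(80 * np.log(2), rel=1e-9)
        assert losses[-1] <= 0.1 * losses[0]
        assert 0.8 * floor <= losses[-1] <= 1.1 * floor

    def test_mil_mode_forces_single_cluster(self):
        cfg = TrainConfig(mode="mil", K=5, T=1)
        assert cfg.K == 1


class TestPredict:
    def test_one_stump_model_hand_scores(self):
        model = one_stump_model(K=2, alpha=0.7)
        bag = Bag("b", 1, np.array([[1.0, 0.0], [-1.0, 0.0]]))
        scores, best, positive = predict_instances(model, bag)
        assert np.allclose(scores, [[0.7, 0.7], [-0.7, -0.7]])
        assert np.array_equal(best, [1, 1])  # tie -> lowest cluster
        assert np.array_equal(positive, [True, False])
        score, label = predict_bag(model, bag)
        assert score == pytest.approx(0.7) and label == 1

    def test_bag_score_is_max_over_instances(self, rng):
        model = one_stump_model(K=3, alpha=0.4)
        bag = Bag("b", -1, rng.standard_normal((6, 2)))
        scores, _, positive = predict_instances(model, bag)
        score, label = predict_bag(model, bag)
        assert score == pytest.approx(scores.max())
        assert (label == 1) == positive.any()

    def test_rejects_dimension_mismatch(self):
        model = one_stump_model(K=1)
        with pytest.raises(ValueError):
            predict_bag(model, Bag("b", 1, np.zeros((2, 5))))


class TestReassignClusters:
    def test_k1_is_identity(self, tiny_dataset):
        model = one_stump_model(K=1)
        bags = [Bag(b.bag_id, b.label, np.hstack([b.instances, b.instances]))
                for b in tiny_dataset]  # match D=2
        current = init_clusters(bags, 1, seed=0)
        new = reassign_clusters(model, bags, current)
        assert all(np.array_equal(new.labels[b], current.labels[b]) for b in new.labels)

    def test_exact_tie_goes_to_cluster_one(self, rng):
        model = one_stump_model(K=3)  # identical classifiers -> all scores tie
        bags = [Bag("p", 1, rng.standard_normal((5, 2))),
                Bag("n", -1, rng.standard_normal((3, 2)))]
        new = reassign_clusters(model, bags, init_clusters(bags, 3, seed=0))
        assert np.all(new.labels["p"] == 1)
        assert "n" not in new.labels

    def test_matches_per_instance_probability_argmax(self, rng):
        stumps = [(float(rng.uniform(0.2, 1.0)),
                   Stump(int(rng.integers(0, 2)), float(rng.standard_normal()),
                         int(rng.choice([-1, 1])), 0.2))
                  for _ in range(6)]
        clfs = [StrongClassifier(k + 1, stumps[2 * k: 2 * k + 2]) for k in range(3)]
        model = MILModel(mode="pmil", K=3, r=20.0, D=2, classifiers=clfs)
        bags = [Bag("p", 1, rng.standard_normal((20, 2))),
                Bag("n", -1, rng.standard_normal((4, 2)))]
        new = reassign_clusters(model, bags, init_clusters(bags, 3, seed=0))
        # oracle: argmax over explicitly computed instance probabilities
        probs = sigmoid(2.0 * model.instance_scores(bags[0].instances))
        expected = np.argmax(probs, axis=1) + 1
        assert np.array_equal(new.labels["p"], expected)

    def test_competition_fixed_point(self):
        """After pmil training the stored assignment is argmax of the model."""
        bags, _ = default_benchmark()
        model = fit(bags, TrainConfig(mode="pmil", K=3, T=4, seed=2))
        again = reassign_clusters(model, bags, model.assignment)
        assert all(np.array_equal(again.labels[b], model.assignment.labels[b])
                   for b in again.labels)
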