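"""Prototype/attention/distance/loss operations vs hand-computed oracles."""

import numpy as np
import pytest

from protoerp import nn
from protoerp.protonet import (AttentionProtoNet, PrototypePair,
                               class_probabilities, classification_loss,
                               classify, compute_prototypes, feature_attention,
                               metric_loss, subject_attention, total_loss,
                               weighted_distance)

DIM = 1024
RNG = np.random.default_rng(19)


def vec(*head):
    v = np.zeros(DIM)
    v[:len(head)] = head
    return v


class TestWeightedDistance:
    def test_coincident_point_is_zero(self):
        f = RNG.standard_normal(DIM)
        assert weighted_distance(f, f, np.ones(DIM)) == 0.0

    def test_unit_weights_reduce_to_squared_euclidean(self):
        assert weighted_distance(vec(3, 4), vec(0, 0), np.ones(DIM)) == pytest.approx(25.0, abs=1e-9)

    def test_elementwise_arithmetic(self):
        # z=(2, 0.5, 0, ...), f-p=(1, 2, 0, ...) -> 2*1 + 0.5*4 = 4
        z = vec(2.0, 0.5)
        assert weighted_distance(vec(1, 2), vec(0, 0), z) == pytest.approx(4.0, abs=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            weighted_distance(vec(1), vec(0), vec(-1))


class TestClassProbabilities:
    def test_symmetry(self):
        assert class_probabilities(3.7, 3.7) == pytest.approx((0.5, 0.5), abs=1e-12)

    def test_nearer_prototype_wins(self):
        # d0=0, d1=ln 3 -> P0 = 1/(1 + 1/3) = 0.75
        p0, p1 = class_probabilities(0.0, np.log(3.0))
        assert p0 == pytest.approx(0.75, abs=1e-12)

    def test_normalization_and_overflow_guard(self):
        d0, d1 = RNG.uniform(0, 2000, size=(2, 50))
        p0, p1 = class_probabilities(d0, d1)
        np.testing.assert_allclose(p0 + p1, 1.0, atol=1e-12)
        assert np.isfinite(p0).all()


class TestClassificationLoss:
    def test_perfect_probabilities(self):
        probs = np.column_stack([np.array([1.0, 0.0]), np.array([0.0, 1.0])])
        assert classification_loss(probs, np.array([0, 1])) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_probabilities_give_ln2(self):
        probs = np.full((8, 2), 0.5)
        labels = np.array([0, 1] * 4)
        assert classification_loss(probs, labels) == pytest.approx(np.log(2), abs=1e-12)

    def test_order_invariance(self):
        probs = RNG.uniform(0.1, 0.9, size=(10, 1))
        probs = np.column_stack([probs, 1 - probs])
        labels = RNG.integers(0, 2, 10)
        perm = RNG.permutation(10)
        assert classification_loss(probs, labels) == pytest.approx(
            classification_loss(probs[perm], labels[perm]), abs=1e-12)


class TestMetricLoss:
    def test_balanced_distances_zero(self):
        d = RNG.uniform(0, 5, 6)
        assert metric_loss(d, d) == 0.0

    def test_arithmetic(self):
        assert metric_loss(np.array([1.0, 2.0]), np.array([3.0, 4.0])) == pytest.approx(-2.0, abs=1e-12)

    def test_monotone_in_same_class_distance(self):
        ds, do = np.array([2.0, 3.0]), np.array([1.0, 1.0])
        base = metric_loss(ds, do)
        assert metric_loss(ds - 0.5, do) < base


class TestTotalLoss:
    def test_lambda_zero(self):
        lb = total_loss(0.7, -0.3, 0.0)
        assert lb.total == pytest.approx(0.7)

    def test_weighted_sum(self):
        lb = total_loss(0.7, -0.3, 1.0)
        assert lb.total == pytest.approx(0.4, abs=1e-12)
        assert lb.class_loss == pytest.approx(0.7)
        assert lb.metric_loss == pytest.approx(-0.3)

    def test_linear_in_metric_term(self):
        t1 = total_loss(1.0, 2.0, 0.5).total
        t2 = total_loss(1.0, 4.0, 0.5).total
        assert t2 - t1 == pytest.approx(1.0, abs=1e-12)


class TestSubjectAttention:
    def test_identical_scores_give_uniform(self):
        support = np.tile(RNG.standard_normal(DIM), (4, 1))
        g = np.eye(DIM)
        alpha = subject_attention(support, support[0], g)
        np.testing.assert_allclose(alpha, 0.25, atol=1e-9)
        assert alpha.sum() == pytest.approx(1.0, abs=1e-12)

    def test_softmax_arithmetic(self):
        # engineered e = (ln 2, 0) -> alpha = (2/3, 1/3)
        alpha = np.exp([np.log(2), 0.0])
        alpha /= alpha.sum()
        np.testing.assert_allclose(alpha, [2 / 3, 1 / 3], atol=1e-12)
        # and the implementation's softmax agrees on the same scores
        support = np.stack([vec(1.0), vec(0.0)])
        got = subject_attention(support, vec(1.0), None, enabled=False)
        np.testing.assert_allclose(got, [0.5, 0.5])

    def test_disabled_gives_uniform(self):
        support = RNG.standard_normal((5, DIM))
        alpha = subject_attention(support, RNG.standard_normal(DIM), None,
                                  enabled=False)
        np.testing.assert_allclose(alpha, 0.2)

    def test_matches_definition_on_random_inputs(self):
        support = RNG.standard_normal((3, DIM))
        query = RNG.standard_normal(DIM)
        g = RNG.standard_normal((DIM, DIM)) / np.sqrt(DIM)
        alpha = subject_attention(support, query, g)
        e = np.array([np.tanh((s @ g) * (query @ g)).sum() for s in support])
        expect = np.exp(e - e.max())
        expect /= expect.sum()
        np.testing.assert_allclose(alpha, expect, rtol=1e-10)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            subject_attention(RNG.standard_normal((2, 10)), np.zeros(10),
                              np.eye(DIM))


class TestComputePrototypes:
    def test_single_subject_weight_one(self):
        means = RNG.standard_normal((1, 2, DIM))
        pair = compute_prototypes(means, np.array([1.0]))
        np.testing.assert_allclose(pair.p0, means[0, 0])
        np.testing.assert_allclose(pair.p1, means[0, 1])

    def test_uniform_alpha_reduces_to_plain_mean(self):
        means = RNG.standard_normal((4, 2, DIM))
        pair = compute_prototypes(means, np.full(4, 0.25))
        np.testing.assert_allclose(pair.p0, means[:, 0].mean(axis=0), rtol=1e-12)

    def test_weighted_mean_arithmetic(self):
        means = np.stack([np.stack([vec(1), vec(1)]), np.stack([vec(0), vec(0)])])
        means[0, :, 1] = 0.0
        means[1, :, 1] = 1.0
        pair = compute_prototypes(means, np.array([0.8, 0.2]))
        np.testing.assert_allclose(pair.p0[:2], [0.8, 0.2], atol=1e-12)

    def test_alpha_must_be_simplex(self):
        with pytest.raises(ValueError, match="sum to 1"):
            compute_prototypes(np.zeros((2, 2, DIM)), np.array([0.9, 0.5]))


class TestFeatureAttention:
    def test_disabled_is_all_ones(self):
        z = feature_attention(RNG.standard_normal((2, DIM)), None, enabled=False)
        np.testing.assert_array_equal(z, np.ones((2, DIM)))

    def test_mean_one_and_nonnegative(self):
        w = RNG.standard_normal(9)
        z = feature_attention(RNG.standard_normal((2, DIM)), w, 0.3)
        assert (z >= 0).all()
        np.testing.assert_allclose(z.mean(axis=1), 1.0, atol=1e-6)

    def test_zeroed_weights_give_uniform_scores(self):
        z = feature_attention(RNG.standard_normal((2, DIM)), np.zeros(9), 0.0)
        np.testing.assert_allclose(z, 1.0, atol=1e-12)


class TestClassify:
    def test_query_at_target_prototype(self):
        pair = PrototypePair(p0=vec(5.0), p1=vec(-1.0))
        labels, probs = classify(pair.p1, pair)
        assert labels[0] == 1
        assert probs[0, 1] > 0.5

    def test_tie_breaks_to_nontarget(self):
        pair = PrototypePair(p0=vec(1.0), p1=vec(-1.0))
        labels, probs = classify(vec(0.0), pair)
        assert labels[0] == 0
        np.testing.assert_allclose(probs[0], [0.5, 0.5])

    def test_matches_bruteforce_nearest_prototype_2d(self):
        """8 hand-placed queries in a 2-D feature plane vs enumeration."""
        pair = PrototypePair(p0=vec(0.0, 0.0), p1=vec(2.0, 1.0))
        queries = np.stack([vec(x, y) for x, y in
                            [(0, 0), (2, 1), (1, 0.5), (3, 3), (-1, -1),
                             (1.5, 1), (0.5, 0), (2, -1)]])
        labels, _ = classify(queries, pair)
        brute = []
        for q in queries:
            d0 = ((q - pair.p0) ** 2).sum()
            d1 = ((q - pair.p1) ** 2).sum()
            brute.append(1 if d1 < d0 else 0)
        np.testing.assert_array_equal(labels, brute)

    def test_common_rescaling_of_z_preserves_decisions(self):
        # small feature dim keeps the softmax away from saturation so the
        # probability ordering is numerically resolvable
        dim = 6
        pair = PrototypePair(p0=RNG.standard_normal(dim) * 0.3,
                             p1=RNG.standard_normal(dim) * 0.3)
        queries = RNG.standard_normal((20, dim)) * 0.3
        z = RNG.uniform(0.1, 2.0, dim)
        l1, p1 = classify(queries, pair, z, z)
        l2, p2 = classify(queries, pair, 1.7 * z, 1.7 * z)
        np.testing.assert_array_equal(l1, l2)
        # probability ordering across queries is preserved too
        np.testing.assert_array_equal(np.argsort(p1[:, 1]), np.argsort(p2[:, 1]))


class TestModelHead:
    """Autograd episode head agrees with the functional reference path."""

    def test_tensor_head_matches_numpy_ops(self, tiny_model):
        m, q = 3, 5
        class_means = RNG.standard_normal((m, 2, DIM)).astype(np.float32)
        queries = RNG.standard_normal((q, DIM)).astype(np.float32)
        dists, alpha, z = tiny_model.episode_forward(
            nn.Tensor(class_means.astype(np.float64)),
            nn.Tensor(queries.astype(np.float64)))
        g = tiny_model.g.weight.data
        z_ref = feature_attention(class_means.mean(axis=0),
                                  tiny_model.fa_weight.data,
                                  float(tiny_model.fa_bias.data[0]))
        alpha_ref = subject_attention(class_means.mean(axis=1), queries, g)
        np.testing.assert_allclose(alpha.data, alpha_ref, rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(z.data, z_ref, rtol=1e-4, atol=1e-6)
        for i in range(q):
            pair = compute_prototypes(class_means, alpha_ref[i])
            for k, p in enumerate((pair.p0, pair.p1)):
                expect = weighted_distance(queries[i], p, z_ref[k])
                assert dists.data[i, k] == pytest.approx(expect, rel=1e-4)

    def test_attention_normalization_contracts(self, tiny_model):
        class_means = nn.Tensor(RNG.standard_normal((4, 2, DIM)))
        queries = nn.Tensor(RNG.standard_normal((6, DIM)))
        _, alpha, z = tiny_model.episode_forward(class_means, queries)
        np.testing.assert_allclose(alpha.data.sum(axis=1), 1.0, atol=1e-6)
        assert (alpha.data >= 0).all()
        np.testing.assert_allclose(z.data.mean(axis=1), 1.0, atol=1e-6)
        assert (z.data >= 0).all()


# -- property-based invariants ----------------------------------------------

from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp


@settings(max_examples=50, deadline=None, derandomize=True)
@given(hnp.arrays(np.float64, (3, 8), elements=st.floats(-10, 10)),
       hnp.arrays(np.float64, (8,), elements=st.floats(0, 5)))
def test_distance_probability_properties(mats, z):
    """Weighted distances are nonnegative and symmetric in their arguments;
    the induced class probabilities form a distribution favoring the
    nearer prototype."""
    f, p0, p1 = mats
    d0 = weighted_distance(f, p0, z)
    d1 = weighted_distance(f, p1, z)
    assert d0 >= 0.0 and d1 >= 0.0
    assert weighted_distance(p0, f, z) == pytest.approx(d0, rel=1e-12, abs=1e-12)
    q0, q1 = class_probabilities(d0, d1)
    assert q0 + q1 == pytest.approx(1.0, abs=1e-12)
    if d0 < d1:
        assert q0 >= q1
    elif d1 < d0:
        assert q1 >= q0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(hnp.arrays(np.float64, (4, 2, 6), elements=st.floats(-5, 5)),
       hnp.arrays(np.float64, (4,), elements=st.floats(0.01, 1.0)))
def test_prototypes_stay_in_convex_hull(means, raw_alpha):
    """Attention-weighted prototypes are convex combinations of the
    per-subject class means (coordinate-wise bounded by their extremes)."""
    alpha = raw_alpha / raw_alpha.sum()
    pair = compute_prototypes(means, alpha)
    for k, p in enumerate((pair.p0, pair.p1)):
        assert (p <= means[:, k].max(axis=0) + 1e-9).all()
        assert (p >= means[:, k].min(axis=0) - 1e-9).all()
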