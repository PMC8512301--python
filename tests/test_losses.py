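"""Loss functions: worked examples, invariants and a brute-force MI oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzyoc import losses
from fuzzyoc.losses import (
    JointDistribution,
    LossWeights,
    ce_inverse_triplet,
    combined_loss,
    cross_entropy,
    inverse_cross_entropy,
    joint_distribution,
    mutual_information,
)


def random_prob_vector(rng, k):
    return rng.dirichlet(np.ones(k))


class TestInverseCrossEntropy:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            # splitting mass over two clusters against a third one-hot output
            # costs nothing -- the motivating property of the loss
            ((0.5, 0.5, 0.0), (0.0, 0.0, 1.0), 0.0),
            ((0.0, 1.0), (1.0, 0.0), 0.0),
            ((1.0, 0.0), (0.5, 0.5), np.log(2)),
        ],
    )
    def test_worked_examples(self, p, q, expected):
        assert inverse_cross_entropy(np.array(p), np.array(q)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            inverse_cross_entropy(np.ones(3) / 3, np.ones(4) / 4)

    def test_eps_range(self):
        with pytest.raises(ValueError):
            inverse_cross_entropy(np.ones(2) / 2, np.ones(2) / 2, eps=0.5)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_nonnegative_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        p = random_prob_vector(rng, 4)
        q = random_prob_vector(rng, 4)
        val = inverse_cross_entropy(p, q)
        assert val >= 0
        # increasing q(c) for a supported c cannot decrease the loss
        c = int(np.argmax(p))
        q2 = q.copy()
        q2[c] = min(q2[c] + 0.1, 0.999)
        assert inverse_cross_entropy(p, q2) >= val - 1e-12

    def test_triplet_combination_and_symmetry(self, rng):
        out1 = np.array([1.0, 0.0])
        out2 = np.array([0.0, 1.0])
        out3 = np.array([0.5, 0.5])
        assert ce_inverse_triplet(out1, out2, out3) == pytest.approx(np.log(2))
        assert ce_inverse_triplet(out1, out2, out3) == pytest.approx(
            ce_inverse_triplet(out2, out1, out3)
        )
        both = np.array([0.5, 0.5, 0.0])
        other = np.array([0.0, 0.0, 1.0])
        assert ce_inverse_triplet(both, both, other) == pytest.approx(0.0, abs=1e-9)


class TestCrossEntropy:
    def test_examples(self):
        assert cross_entropy(0, np.array([1.0, 0.0])) == pytest.approx(0.0, abs=2e-6)
        assert cross_entropy(0, np.array([0.5, 0.5])) == pytest.approx(np.log(2))
        k = 5
        u = np.ones(k) / k
        assert cross_entropy(u, u) == pytest.approx(np.log(k))


class TestJointDistribution:
    def test_single_one_hot_pair(self):
        e1 = np.array([1.0, 0.0])
        J = joint_distribution([e1], [e1])
        np.testing.assert_allclose(J.P, [[1, 0], [0, 0]], atol=1e-12)

    def test_two_diagonal_pairs(self):
        # brute-force outer-product average of (e1,e1) and (e2,e2)
        e1, e2 = np.eye(2)
        J = joint_distribution([e1, e2], [e1, e2])
        np.testing.assert_allclose(J.P, np.diag([0.5, 0.5]), atol=1e-12)

    @given(st.integers(0, 2**32 - 1), st.integers(2, 6), st.integers(1, 8))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_normalized_and_swap_invariant(self, seed, k, n):
        rng = np.random.default_rng(seed)
        a = rng.dirichlet(np.ones(k), n)
        b = rng.dirichlet(np.ones(k), n)
        J1 = joint_distribution(a, b)
        J2 = joint_distribution(b, a)
        np.testing.assert_allclose(J1.P, J1.P.T, atol=1e-12)
        assert J1.P.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(J1.P, J2.P, atol=1e-12)

    def test_empty_batch(self):
        with pytest.raises(ValueError):
            joint_distribution(np.empty((0, 2)), np.empty((0, 2)))

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            JointDistribution(np.array([[0.9, 0.0], [0.0, 0.0]]))  # not normalized
        with pytest.raises(ValueError):
            JointDistribution(np.array([[0.5, 0.3], [0.2, 0.0]]))  # not symmetric


def mi_bruteforce(P, eps=1e-12):
    """Independent double-loop oracle for the mutual information."""
    k = P.shape[0]
    pc = [sum(P[c][cc] for cc in range(k)) for c in range(k)]
    total = 0.0
    for c in range(k):
        for cc in range(k):
            if P[c][cc] > 0:
                total += P[c][cc] * (
                    np.log(max(P[c][cc], eps)) - np.log(max(pc[c] * pc[cc], eps))
                )
    return total


class TestMutualInformation:
    @pytest.mark.parametrize("k", [2, 3, 6])
    def test_perfectly_correlated_uniform(self, k):
        assert mutual_information(np.eye(k) / k) == pytest.approx(np.log(k))

    @pytest.mark.parametrize("k", [2, 5])
    def test_independent_uniform(self, k):
        assert mutual_information(np.full((k, k), 1 / k**2)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = int(rng.integers(2, 11))
            Q = rng.dirichlet(np.ones(k * k)).reshape(k, k)
            P = (Q + Q.T) / 2
            assert mutual_information(P) == pytest.approx(
                mi_bruteforce(P), abs=1e-10
            )
            assert mutual_information(P) >= -1e-9

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            mutual_information(np.ones((3, 3)))


class TestCombinedLoss:
    def test_weighted_sum(self):
        assert combined_loss(0.2, 0.3, LossWeights(1, 1)) == pytest.approx(0.5)

    def test_warmup_and_light_configurations(self):
        # lambda_s = 0 leaves only the unsupervised term (warm-up);
        # lambda_u = 0 leaves only the supervised term (the light variant)
        assert combined_loss(5.0, 0.3, LossWeights(0.0, 1.0)) == pytest.approx(0.3)
        assert combined_loss(0.2, 9.0, LossWeights(1.0, 0.0)) == pytest.approx(0.2)

    @given(
        st.floats(0, 10), st.floats(0, 10), st.floats(0, 3), st.floats(0, 3)
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, ls, lu, ws, wu):
        w = LossWeights(ws, wu)
        assert combined_loss(2 * ls, lu, w) - combined_loss(ls, lu, w) == pytest.approx(
            ws * ls, rel=1e-9, abs=1e-9
        )

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-0.1, 1.0)


class TestBatchGradients:
    """Finite-difference checks of the analytic gradients the trainer uses."""

    def _fd(self, f, arr, g, eps=1e-7):
        flat = arr.ravel()
        for j in range(flat.size):
            old = flat[j]
            flat[j] = old + eps
            up = f()
            flat[j] = old - eps
            down = f()
            flat[j] = old
            num = (up - down) / (2 * eps)
            assert num == pytest.approx(g.ravel()[j], rel=1e-4, abs=1e-7)

    def test_inverse_ce_gradients(self, rng):
        p = rng.dirichlet(np.ones(4), 5)
        q = rng.dirichlet(np.ones(4), 5)
        _, gp, gq = losses.batch_inverse_cross_entropy(p, q)
        self._fd(lambda: losses.batch_inverse_cross_entropy(p, q)[0], p, gp)
        self._fd(lambda: losses.batch_inverse_cross_entropy(p, q)[0], q, gq)

    def test_mi_gradients(self, rng):
        a = rng.dirichlet(np.ones(3), 6)
        b = rng.dirichlet(np.ones(3), 6)
        _, ga, gb = losses.batch_mi_loss(a, b)
        self._fd(lambda: losses.batch_mi_loss(a, b)[0], a, ga)
        self._fd(lambda: losses.batch_mi_loss(a, b)[0], b, gb)

    def test_fused_ce_matches_prob_space_path(self, rng):
        from fuzzyoc import nn

        logits = rng.normal(0, 2, (7, 4)).astype(np.float32)
        p = nn.softmax(logits)
        y = rng.integers(0, 4, 7)
        l_prob, g_prob = losses.batch_cross_entropy(p, y)
        l_fused, dz_fused = losses.batch_cross_entropy_logits(p, y)
        assert l_prob == pytest.approx(l_fused)
        np.testing.assert_allclose(
            nn.softmax_backward(p, g_prob), dz_fused, atol=1e-6
        )
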