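"""Loss functions: analytic limits, brute-force oracles, invariances and the
learning-rate schedule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import surgphase as sp
from surgphase import nn
from surgphase.exceptions import DegenerateInputError


def naive_contrastive(X, Y, tau, symmetric=False):
    """Independent double-loop evaluation of the contrastive loss."""
    n = len(X)
    total = 0.0
    for i in range(n):
        num = np.exp(sp.cosine_similarity(X[i], Y[i]) / tau)
        den = sum(
            np.exp(sp.cosine_similarity(X[i], Y[j]) / tau) for j in range(n)
        )
        total += -np.log(num / den)
    loss = total / n
    if symmetric:
        return 0.5 * (loss + naive_contrastive(Y, X, tau))
    return loss


class TestCosineSimilarity:
    def test_identical_vectors(self):
        assert sp.cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert sp.cosine_similarity([1, 0], [0, 5]) == pytest.approx(0.0)

    def test_forty_five_degrees(self):
        assert sp.cosine_similarity([1, 0], [1, 1]) == pytest.approx(
            1 / np.sqrt(2)
        )

    def test_zero_vector_rejected_not_silently_zero(self):
        with pytest.raises(DegenerateInputError):
            sp.cosine_similarity([0, 0], [1, 1])


class TestContrastiveLoss:
    def test_single_pair_is_exactly_zero(self, rng):
        x = rng.normal(size=(1, 4))
        assert sp.multimodal_contrastive_loss(x, x * 2.0, tau=0.1) == 0.0

    @pytest.mark.parametrize("n", [2, 5, 16])
    def test_constant_similarity_batch_gives_log_n(self, n):
        X = np.ones((n, 3))
        assert sp.multimodal_contrastive_loss(X, X, tau=0.1) == pytest.approx(
            np.log(n), abs=1e-12
        )

    @pytest.mark.parametrize("tau", [0.05, 0.1, 1.0])
    @pytest.mark.parametrize("symmetric", [False, True])
    def test_matches_double_loop_oracle_on_seeded_batches(self, tau, symmetric):
        rng = np.random.default_rng(int(tau * 100) + symmetric)
        for _ in range(50):
            n = rng.integers(2, 9)
            d = rng.integers(2, 17)
            X = rng.normal(size=(n, d))
            Y = rng.normal(size=(n, d))
            ours = sp.multimodal_contrastive_loss(X, Y, tau, symmetric)
            ref = naive_contrastive(X, Y, tau, symmetric)
            assert ours == pytest.approx(ref, rel=1e-12, abs=1e-12)

    def test_zero_norm_row_rejected(self):
        X = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(DegenerateInputError):
            sp.multimodal_contrastive_loss(X, np.ones((2, 2)), 0.1)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_under_joint_row_permutation(self, seed):
        rng = np.random.default_rng(seed)
        X, Y = rng.normal(size=(2, 5, 3))
        perm = rng.permutation(5)
        a = sp.multimodal_contrastive_loss(X, Y, 0.1)
        b = sp.multimodal_contrastive_loss(X[perm], Y[perm], 0.1)
        assert a == pytest.approx(b, rel=1e-12)

    def test_invariant_to_positive_row_rescaling(self, rng):
        X, Y = rng.normal(size=(2, 4, 3))
        X2 = X.copy()
        X2[1] *= 37.0
        a = sp.multimodal_contrastive_loss(X, Y, 0.1)
        b = sp.multimodal_contrastive_loss(X2, Y, 0.1)
        assert a == pytest.approx(b, rel=1e-12)

    def test_strictly_decreases_when_matched_pair_aligns(self, rng):
        X, Y = rng.normal(size=(2, 4, 3))
        base = sp.multimodal_contrastive_loss(X, Y, 0.1)
        Y2 = Y.copy()
        # move y_0 toward x_0 (increases only sim(x_0, y_0) materially)
        Y2[0] = 0.5 * Y2[0] / np.linalg.norm(Y2[0]) + 0.5 * X[0] / np.linalg.norm(X[0])
        closer = sp.multimodal_contrastive_loss(X, Y2, 0.1)
        assert closer < base

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(4, 3))
        Y = rng.normal(size=(4, 3))
        xt = nn.Tensor(X, requires_grad=True)
        yt = nn.Tensor(Y, requires_grad=True)
        sp.multimodal_contrastive_loss(xt, yt, tau=0.1).backward()
        eps = 1e-6
        for t, arr, other, first in ((xt, X, Y, True), (yt, Y, X, False)):
            fd = np.zeros_like(arr)
            for i in range(arr.shape[0]):
                for j in range(arr.shape[1]):
                    hi, lo = arr.copy(), arr.copy()
                    hi[i, j] += eps
                    lo[i, j] -= eps
                    if first:
                        fhi = sp.multimodal_contrastive_loss(hi, other, 0.1)
                        flo = sp.multimodal_contrastive_loss(lo, other, 0.1)
                    else:
                        fhi = sp.multimodal_contrastive_loss(other, hi, 0.1)
                        flo = sp.multimodal_contrastive_loss(other, lo, 0.1)
                    fd[i, j] = (fhi - flo) / (2 * eps)
            np.testing.assert_allclose(t.grad, fd, atol=1e-5)


class TestNCELoss:
    def test_equal_densities_give_log_two(self):
        p = np.array([0.3, 0.7, 0.5])
        assert sp.nce_loss(p, p, k=1) == pytest.approx(np.log(2), abs=1e-12)

    def test_zero_noise_gives_zero_loss(self):
        p = np.array([0.2, 0.9])
        assert sp.nce_loss(p, np.zeros(2), k=3) == 0.0

    def test_hand_computed_example(self):
        p = np.array([0.9, 0.5])
        pn = np.array([0.1, 0.5])
        expected = -0.5 * (
            np.log(0.9 / (0.9 + 2 * 0.1)) + np.log(0.5 / (0.5 + 2 * 0.5))
        )
        assert sp.nce_loss(p, pn, k=2) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_denominator_rejected(self):
        with pytest.raises(DegenerateInputError):
            sp.nce_loss([0.0, 0.5], [0.0, 0.5], k=1)


class TestCrossEntropy:
    def test_one_hot_correct_prediction(self):
        assert sp.cross_entropy([0.0, 1.0, 0.0], 1) == 0.0

    def test_uniform_over_seven_phases(self):
        assert sp.cross_entropy(np.full(7, 1 / 7), 3) == pytest.approx(
            np.log(7)
        )

    def test_direct_evaluation(self):
        assert sp.cross_entropy([0.7, 0.2, 0.1], 1) == pytest.approx(
            -np.log(0.2)
        )

    def test_invalid_label_and_non_simplex_rejected(self):
        with pytest.raises(IndexError):
            sp.cross_entropy([0.5, 0.5], 2)
        with pytest.raises(ValueError):
            sp.cross_entropy([0.5, 0.6], 0)


class TestLRSchedule:
    def test_warmup_endpoint_is_exactly_base_lr(self):
        assert sp.lr_schedule(50, 0.001, 5, 50, 10) == 0.001

    def test_final_step_reaches_floor(self):
        assert sp.lr_schedule(500, 0.001, 5, 50, 10) == pytest.approx(0.0)

    def test_decay_midpoint_is_half(self):
        # warmup 50 steps, decay over 450: midpoint at step 275
        assert sp.lr_schedule(275, 0.001, 5, 50, 10) == pytest.approx(0.0005)

    def test_ramp_is_linear_from_zero(self):
        assert sp.lr_schedule(0, 0.001, 5, 50, 10) == 0.0
        assert sp.lr_schedule(25, 0.001, 5, 50, 10) == pytest.approx(0.0005)

    def test_invalid_warmup_rejected(self):
        with pytest.raises(ValueError):
            sp.lr_schedule(0, 0.001, 50, 50, 10)
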