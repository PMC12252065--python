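"""Loss-function oracles: hand-computed values, reduction identities,
gradient checks, and the margin-gating property."""

import numpy as np
import pytest

from harspectrum.losses import (LossWeights, contrastive_loss,
                                cross_entropy_from_logits, cross_entropy_loss,
                                feature_consistency_loss, multitask_loss,
                                reconstruction_loss, selfsup_loss,
                                similarity_distance, temporal_consistency_loss,
                                weak_selfsup_loss)
from harspectrum.nn import Tensor


def numeric_grad(fn, x, eps=1e-6):
    g = np.zeros_like(x)
    for idx in np.ndindex(*x.shape):
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        g[idx] = (fn(xp) - fn(xm)) / (2 * eps)
    return g


class TestReconstruction:
    def test_perfect_reconstruction_is_zero(self):
        x = np.random.default_rng(0).normal(size=(4, 5))
        assert float(reconstruction_loss(x, x)) == 0.0

    def test_hand_value(self):
        assert float(reconstruction_loss([[0.0, 0.0]], [[3.0, 4.0]])) == 25.0

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(1)
        x, r = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        base = float(reconstruction_loss(x, r))
        doubled = float(reconstruction_loss(x, x + 2 * (r - x)))
        assert doubled == pytest.approx(4 * base, rel=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 3)), np.zeros((2, 4)))


class TestSimilarityDistance:
    def test_identity_and_hand_value(self):
        assert float(similarity_distance([1.0, 2.0], [1.0, 2.0])) == pytest.approx(0, abs=1e-9)
        assert float(similarity_distance([0.0, 0.0], [3.0, 4.0])) == pytest.approx(5, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(size=8)
        assert float(similarity_distance(a, b)) == pytest.approx(
            float(similarity_distance(b, a)), abs=1e-12)


class TestContrastive:
    def test_similar_identical_pair_is_zero(self):
        t, _ = contrastive_loss([[1.0, 1.0]], [[1.0, 1.0]], [1])
        assert float(t) == pytest.approx(0, abs=1e-9)

    def test_margin_satisfied_negative_is_zero(self):
        t, bd = contrastive_loss([[0.0, 0.0]], [[5.0, 0.0]], [0], delta=1.0)
        assert float(t) == 0.0
        assert bd.Ld[0] == 0.0

    def test_hand_values(self):
        t, bd = contrastive_loss([[0.0, 0.0]], [[3.0, 4.0]], [1])
        assert float(t) == pytest.approx(12.5, abs=1e-9)
        assert bd.Ls[0] == pytest.approx(12.5, abs=1e-9)
        t, _ = contrastive_loss([[0.0, 0.0]], [[0.5, 0.0]], [0], delta=1.0)
        assert float(t) == pytest.approx(0.125, abs=1e-9)

    def test_breakdown_consistency(self):
        rng = np.random.default_rng(3)
        fa, fb = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        y = np.array([1, 0, 1, 0, 1, 0])
        t, bd = contrastive_loss(fa, fb, y, delta=1.5)
        assert np.allclose(bd.Ls, bd.D ** 2 / 2, atol=1e-9)
        assert np.allclose(bd.Ld, np.maximum(0, 1.5 - bd.D) ** 2 / 2, atol=1e-9)
        assert np.allclose(bd.per_pair_loss, y * bd.Ls + (1 - y) * bd.Ld)
        assert float(t) == pytest.approx(bd.per_pair_loss.sum(), abs=1e-10)

    def test_hard_negative_gating(self):
        # negatives beyond the margin contribute exactly zero for all D >= delta
        for d in (1.0, 1.5, 4.0):
            t, _ = contrastive_loss([[0.0]], [[d]], [0], delta=1.0)
            assert float(t) == 0.0

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError):
            contrastive_loss([[0.0]], [[1.0]], [0.5])

    def test_gradcheck(self):
        rng = np.random.default_rng(4)
        fav, fbv = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        y = np.array([1, 0, 0, 1, 0])
        fa = Tensor(fav, requires_grad=True)
        t, _ = contrastive_loss(fa, fbv, y, delta=2.0)
        t.backward()
        num = numeric_grad(
            lambda v: float(contrastive_loss(v, fbv, y, delta=2.0)[0].value), fav)
        assert np.allclose(fa.grad, num, atol=1e-4)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        y = np.eye(3)[[0, 1]]
        assert float(cross_entropy_loss(y, y)) == pytest.approx(0, abs=1e-12)

    def test_uniform_prediction_is_log_m(self):
        m = 4
        y = np.eye(m)[[2]]
        p = np.full((1, m), 1 / m)
        assert float(cross_entropy_loss(y, p)) == pytest.approx(np.log(m), abs=1e-12)

    def test_only_true_class_term_matters(self):
        y = np.eye(3)[[0]]
        p1 = np.array([[0.5, 0.3, 0.2]])
        p2 = np.array([[0.5, 0.1, 0.4]])
        assert float(cross_entropy_loss(y, p1)) == pytest.approx(
            float(cross_entropy_loss(y, p2)), abs=1e-12)

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.eye(2)[[0]], np.array([[0.9, 0.5]]))

    def test_logits_path_matches_probability_path_and_gradcheck(self):
        rng = np.random.default_rng(5)
        zv = rng.normal(size=(4, 3))
        y = np.eye(3)[[0, 2, 1, 0]]
        p = np.exp(zv) / np.exp(zv).sum(axis=1, keepdims=True)
        assert float(cross_entropy_from_logits(zv, y)) == pytest.approx(
            float(cross_entropy_loss(y, p)), abs=1e-10)
        z = Tensor(zv, requires_grad=True)
        cross_entropy_from_logits(z, y).backward()
        num = numeric_grad(
            lambda v: float(cross_entropy_from_logits(v, y).value), zv)
        assert np.allclose(z.grad, num, atol=1e-5)


class TestMultitask:
    def test_hand_value(self):
        assert float(multitask_loss(2.0, 4.0, 0.7, 0.3)) == pytest.approx(2.6)

    def test_beta_zero_reduces_to_single_task(self):
        assert float(multitask_loss(3.3, 9.9, 0.5, 0.0)) == pytest.approx(0.5 * 3.3)

    def test_symmetry_at_equal_weights(self):
        assert float(multitask_loss(2.0, 5.0, 0.4, 0.4)) == pytest.approx(
            float(multitask_loss(5.0, 2.0, 0.4, 0.4)))


class TestConsistency:
    def test_consensus_is_zero(self):
        r = np.array([1.0, 2.0])
        assert float(temporal_consistency_loss(r, [r, r, r])) == pytest.approx(0, abs=1e-12)

    def test_single_neighbor_reduces_to_reconstruction(self):
        x = np.array([1.0, -1.0])
        r = np.array([0.5, 0.5])
        assert float(temporal_consistency_loss(r, [x])) == pytest.approx(
            float(reconstruction_loss(x[None], r[None])), abs=1e-12)

    def test_hand_value(self):
        assert float(temporal_consistency_loss(np.array([0.0]),
                                               [np.array([1.0]), np.array([3.0])])) == 5.0
        assert float(feature_consistency_loss(np.array([0.0]),
                                              [np.array([1.0]), np.array([3.0])])) == 5.0


class TestJointLosses:
    def _toy(self):
        # one sample engineered to per-sample terms ae=1, tc=2, fc=3
        x = np.array([[0.0]])
        recon = Tensor(np.array([[1.0]]), requires_grad=True)
        tc_n = [np.array([[1 + np.sqrt(2.0)]])]
        fc_n = [np.array([[1 + np.sqrt(3.0)]])]
        return x, recon, tc_n, fc_n

    def test_selfsup_hand_value_and_resum(self):
        x, recon, tc_n, fc_n = self._toy()
        total, parts = selfsup_loss(x, recon, tc_n, fc_n,
                                    LossWeights(alpha=0.3, beta=0.3))
        assert float(total) == pytest.approx(1.9, abs=1e-9)
        assert sum(parts.values()) == pytest.approx(float(total), abs=1e-10)

    def test_selfsup_alpha_beta_zero_reduces_to_reconstruction(self):
        x, recon, tc_n, fc_n = self._toy()
        total, _ = selfsup_loss(x, recon, tc_n, fc_n, LossWeights(alpha=0, beta=0))
        assert float(total) == pytest.approx(
            float(reconstruction_loss(x, recon, reduction="sum")), abs=1e-12)

    def test_selfsup_consensus_zero(self):
        r = np.array([[2.0, 2.0]])
        total, _ = selfsup_loss(r, Tensor(r.copy()), [r[0][None]], [r[0][None]],
                                LossWeights(alpha=1.0, beta=0.0))
        assert float(total) == pytest.approx(0, abs=1e-12)

    def test_selfsup_gradcheck(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(3, 2))
        rv = rng.normal(size=(3, 2))
        tc_n = [rng.normal(size=(3, 2)) for _ in range(3)]
        fc_n = [rng.normal(size=(5, 2)) for _ in range(3)]
        w = LossWeights(alpha=0.25, beta=0.35)
        r = Tensor(rv, requires_grad=True)
        total, _ = selfsup_loss(x, r, tc_n, fc_n, w)
        total.backward()
        num = numeric_grad(
            lambda v: float(selfsup_loss(x, Tensor(v), tc_n, fc_n, w)[0].value), rv)
        assert np.allclose(r.grad, num, atol=1e-4)

    def test_weak_selfsup_hand_value(self):
        # per branch: ae=1 each, tc=2 each, fc=3 each; contrastive term = 4
        x = np.array([[0.0]])
        ra = Tensor(np.array([[1.0]]))
        rb = Tensor(np.array([[1.0]]))
        tc_n = [np.array([[1 + np.sqrt(2.0)]])]
        fc_n = [np.array([[1 + np.sqrt(3.0)]])]
        # similar pair at distance D with y=1 gives D^2/2 = 4 -> D = 2*sqrt(2)
        ea = np.array([[0.0]])
        eb = np.array([[2 * np.sqrt(2.0)]])
        w = LossWeights(alpha=0.1, beta=0.1, gamma=0.6)
        total, parts = weak_selfsup_loss(x, x, ra, rb, ea, eb, [1],
                                         tc_n, fc_n, tc_n, fc_n, w)
        assert float(total) == pytest.approx(3.8, abs=1e-9)
        assert sum(parts.values()) == pytest.approx(float(total), abs=1e-10)

    def test_weak_selfsup_gamma_zero_is_two_branch_selfsup(self):
        rng = np.random.default_rng(7)
        xa, xb = rng.normal(size=(2, 3, 2))
        ra, rb = rng.normal(size=(2, 3, 2))
        tc = [rng.normal(size=(2, 2)) for _ in range(3)]
        fc = [rng.normal(size=(4, 2)) for _ in range(3)]
        w0 = LossWeights(alpha=0.2, beta=0.2, gamma=0.0)
        total, _ = weak_selfsup_loss(xa, xb, ra, rb, rng.normal(size=(3, 2)),
                                     rng.normal(size=(3, 2)), [1, 0, 1],
                                     tc, fc, tc, fc, w0)
        sa, _ = selfsup_loss(xa, ra, tc, fc, LossWeights(alpha=0.2, beta=0.2))
        sb, _ = selfsup_loss(xb, rb, tc, fc, LossWeights(alpha=0.2, beta=0.2))
        assert float(total) == pytest.approx(float(sa) + float(sb), abs=1e-10)

    def test_weak_selfsup_pure_contrastive_at_gamma_one(self):
        rng = np.random.default_rng(8)
        ea, eb = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        y = [1, 0, 1]
        x = rng.normal(size=(3, 2))
        r = Tensor(rng.normal(size=(3, 2)))
        nb = [rng.normal(size=(2, 2)) for _ in range(3)]
        w1 = LossWeights(alpha=0.0, beta=0.0, gamma=1.0)
        total, _ = weak_selfsup_loss(x, x, r, r, ea, eb, y, nb, nb, nb, nb, w1)
        ref, _ = contrastive_loss(ea, eb, y, delta=w1.margin_delta)
        assert float(total) == pytest.approx(float(ref), abs=1e-10)

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=0.6, beta=0.6)
        with pytest.raises(ValueError):
            LossWeights(alpha=-0.1)
        with pytest.raises(ValueError):
            LossWeights(margin_delta=0.0)


def test_all_losses_nonnegative_on_random_inputs():
    rng = np.random.default_rng(9)
    for _ in range(20):
        x, r = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        assert float(reconstruction_loss(x, r)) >= 0
        y = rng.integers(0, 2, 4)
        t, _ = contrastive_loss(x, r, y, delta=1.0)
        assert float(t) >= 0
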