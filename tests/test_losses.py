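"""Loss identities, hand-derived values, invariances, and
finite-difference gradient verification for every objective."""

import numpy as np
import pytest

from unitednet.autodiff import Tensor
from unitednet.losses import (
    adaptive_sigma,
    adversarial_losses,
    classification_loss,
    clustering_loss,
    compose_group_loss,
    compose_pgc_loss,
    contrastive_loss,
    prediction_losses,
    similarity_kernel,
)


def finite_diff(f, x, eps=1e-6):
    g = np.zeros_like(x)
    flat, gf = x.ravel(), g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f()
        flat[i] = orig - eps
        lo = f()
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


def check_grad(loss_fn, arrays, rtol=1e-4):
    """Autodiff gradients vs central differences for every input array."""
    tensors = [Tensor(a.copy(), requires_grad=True) for a in arrays]
    out = loss_fn(*tensors)
    out.backward()
    for t, a in zip(tensors, arrays):
        fd = finite_diff(lambda: loss_fn(*[Tensor(x.data) for x in tensors]).item(), t.data)
        scale = np.maximum(np.abs(fd), 1e-3)
        np.testing.assert_allclose(
            (t.grad if t.grad is not None else np.zeros_like(t.data)) / scale,
            fd / scale,
            rtol=rtol,
            atol=1e-6,
        )


class TestSimilarityKernel:
    def test_structure(self, rng):
        S = similarity_kernel(Tensor(rng.standard_normal((6, 3))), sigma=0.8).data
        np.testing.assert_allclose(np.diag(S), 1.0)
        np.testing.assert_allclose(S, S.T)
        assert (S > 0).all() and (S <= 1).all()

    def test_adaptive_sigma_scale_invariance(self, rng):
        h = rng.standard_normal((20, 4))
        assert np.isclose(adaptive_sigma(3 * h, 0.3), 3 * adaptive_sigma(h, 0.3))


class TestClusteringLoss:
    def test_entropy_term_at_uniform(self, rng):
        K, n = 4, 40
        alpha = np.full((n, K), 1.0 / K)
        h = rng.standard_normal((n, 5))
        *_, l_c3 = clustering_loss(Tensor(h), Tensor(alpha), sigma=1.0)
        assert np.isclose(l_c3.item(), -np.log(K), atol=1e-9)

    def test_entropy_term_degenerate(self, rng):
        n, K = 30, 3
        alpha = np.zeros((n, K))
        alpha[:, 0] = 1.0
        h = rng.standard_normal((n, 5))
        *_, l_c3 = clustering_loss(Tensor(h), Tensor(alpha), sigma=1.0)
        assert np.isclose(l_c3.item(), 0.0, atol=1e-6)

    def test_entropy_minimum_is_uniform(self, rng):
        # random perturbations of the uniform mean assignment raise L_c3
        K, n = 3, 60
        h = rng.standard_normal((n, 4))
        base = np.full((n, K), 1.0 / K)
        *_, l_min = clustering_loss(Tensor(h), Tensor(base), sigma=1.0)
        for _ in range(20):
            logits = rng.standard_normal((n, K)) * 0.5
            alpha = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
            *_, l = clustering_loss(Tensor(h), Tensor(alpha), sigma=1.0)
            assert l.item() >= l_min.item() - 1e-12

    def test_separated_blobs_give_small_component1(self, rng):
        n_half = 25
        h = np.vstack(
            [
                rng.standard_normal((n_half, 3)) * 0.1,
                rng.standard_normal((n_half, 3)) * 0.1 + 50.0,
            ]
        )
        alpha = np.vstack(
            [
                np.tile([0.98, 0.02], (n_half, 1)),
                np.tile([0.02, 0.98], (n_half, 1)),
            ]
        )
        l_c1, _, _ = clustering_loss(Tensor(h), Tensor(alpha), sigma=1.0)
        assert l_c1.item() < 0.05

    def test_permutation_invariance(self, rng):
        n, K = 20, 3
        h = rng.standard_normal((n, 4))
        logits = rng.standard_normal((n, K))
        alpha = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        ref = clustering_loss(Tensor(h), Tensor(alpha), sigma=0.7)
        perm = rng.permutation(n)
        out = clustering_loss(Tensor(h[perm]), Tensor(alpha[perm]), sigma=0.7)
        for a, b in zip(ref, out):
            assert np.isclose(a.item(), b.item(), atol=1e-10)

    def test_bounds(self, rng):
        n, K = 30, 4
        h = rng.standard_normal((n, 5))
        logits = rng.standard_normal((n, K))
        alpha = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        l1, l2, l3 = clustering_loss(Tensor(h), Tensor(alpha), sigma=0.5)
        assert 0 <= l1.item() <= 1 and 0 <= l2.item() <= 1
        assert -np.log(K) - 1e-9 <= l3.item() <= 0

    def test_gradients(self, rng):
        n, K = 8, 3
        h0 = rng.standard_normal((n, 4))
        logits0 = rng.standard_normal((n, K))

        def loss(h, logits):
            alpha = logits.softmax(axis=-1)
            l1, l2, l3 = clustering_loss(h, alpha, sigma=0.9)
            return l1 + l2 + l3

        check_grad(loss, [h0, logits0])


class TestPredictionLosses:
    def test_perfect_reconstruction_is_zero(self, rng):
        X = [rng.standard_normal((4, 3)), rng.standard_normal((4, 2))]
        l_w, l_c = prediction_losses(
            X,
            [Tensor(X[0]), Tensor(X[1])],
            {(0, 1): Tensor(X[1])},
            [False, False],
        )
        assert l_w.item() < 1e-5 and l_c.item() < 1e-5

    def test_unit_residual_cross_term(self):
        # one cell, cross prediction off by a unit vector -> loss 1
        X = [np.zeros((1, 3)), np.zeros((1, 3))]
        pred = np.array([[1.0, 0.0, 0.0]])
        l_w, l_c = prediction_losses(
            X,
            [Tensor(X[0]), Tensor(X[1])],
            {(0, 1): Tensor(pred)},
            [False, False],
        )
        assert np.isclose(l_c.item(), 1.0, atol=1e-5)

    def test_binary_modality_uses_bce(self):
        target = np.array([[1.0, 0.0]])
        good = Tensor(np.array([[1.0, 0.0]]))
        l_w, _ = prediction_losses(
            [target], [good], {}, [True]
        )
        assert l_w.item() < 1e-6

    def test_binary_prediction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            prediction_losses(
                [np.array([[1.0]])], [Tensor(np.array([[1.5]]))], {}, [True]
            )

    def test_gradients(self, rng):
        X = [rng.standard_normal((5, 3)), rng.standard_normal((5, 4))]

        def loss(w0, w1, c01):
            l_w, l_c = prediction_losses(X, [w0, w1], {(0, 1): c01}, [False, False])
            return l_w + l_c

        check_grad(
            loss,
            [rng.standard_normal((5, 3)), rng.standard_normal((5, 4)), rng.standard_normal((5, 4))],
        )


class TestAdversarialLosses:
    def test_generator_optimum(self):
        fake = [Tensor(np.ones((4, 1)))]
        l_gen, _ = adversarial_losses(fake, fake)
        assert l_gen.item() == 0.0

    def test_discriminator_optimum(self):
        real = [Tensor(np.ones((4, 1)))]
        fake = [Tensor(np.zeros((4, 1)))]
        _, l_dis = adversarial_losses(real, fake)
        assert l_dis.item() == 0.0

    def test_half_scores_generator_value(self):
        fake = [Tensor(np.full((3, 1), 0.5))]
        l_gen, _ = adversarial_losses(fake, fake)
        assert np.isclose(l_gen.item(), 0.25)

    def test_gradients(self, rng):
        def loss(r, f):
            l_gen, l_dis = adversarial_losses([r], [f])
            return l_gen + l_dis

        check_grad(loss, [rng.standard_normal((6, 1)), rng.standard_normal((6, 1))])


class TestContrastiveLoss:
    def _orthogonal_codes(self):
        # cell 0 in its own group; identical codes across modalities;
        # all cells mutually orthogonal -> every negative similarity is 0
        z = np.eye(3)
        return [Tensor(z.copy()), Tensor(z.copy())], np.array([1, 2, 2])

    def test_derived_value_log2_minus_1(self):
        codes, groups = self._orthogonal_codes()
        l = contrastive_loss(
            codes, groups, tau=1.0, delta=1.0, neg_size=2,
            rng=np.random.default_rng(0),
        )
        # every cell: positive similarity 1, two zero negatives
        assert np.isclose(l.item(), np.log(2.0) - 1.0, atol=1e-9)

    def test_parallel_codes_maximize_positive(self, rng):
        z1 = rng.standard_normal((4, 5))
        codes = [Tensor(z1), Tensor(z1 * 3.0)]  # parallel rows
        groups = np.array([1, 2, 1, 2])
        normed = [c.data / np.linalg.norm(c.data, axis=1, keepdims=True) for c in codes]
        sims = normed[0] @ normed[1].T
        np.testing.assert_allclose(np.diag(sims), 1.0, atol=1e-12)

    def test_delta_scales_linearly(self):
        codes, groups = self._orthogonal_codes()
        kw = dict(tau=1.0, neg_size=2)
        a = contrastive_loss(codes, groups, delta=1.0, rng=np.random.default_rng(3), **kw)
        b = contrastive_loss(codes, groups, delta=2.5, rng=np.random.default_rng(3), **kw)
        assert np.isclose(b.item(), 2.5 * a.item())

    def test_reproducible_given_seed(self, rng):
        codes = [Tensor(rng.standard_normal((12, 4))) for _ in range(2)]
        groups = np.array([1, 2, 3] * 4)
        a = contrastive_loss(codes, groups, 0.1, 1.0, 4, np.random.default_rng(9))
        b = contrastive_loss(codes, groups, 0.1, 1.0, 4, np.random.default_rng(9))
        assert a.item() == b.item()

    def test_all_same_group_skips_with_warning(self, rng, caplog):
        codes = [Tensor(rng.standard_normal((4, 3))) for _ in range(2)]
        l = contrastive_loss(
            codes, np.ones(4, dtype=int), 0.1, 1.0, 4, np.random.default_rng(0)
        )
        assert l.item() == 0.0

    def test_gradients(self, rng):
        groups = np.array([1, 2, 1, 2, 3, 3])

        def loss(z1, z2):
            return contrastive_loss(
                [z1, z2], groups, tau=0.5, delta=1.0, neg_size=3,
                rng=np.random.default_rng(4),
            )

        check_grad(loss, [rng.standard_normal((6, 4)), rng.standard_normal((6, 4))])


class TestClassificationLoss:
    def test_confident_correct_is_zero(self):
        alpha = Tensor(np.array([[1.0, 0.0]]))
        assert classification_loss(alpha, np.array([1])).item() < 1e-6

    def test_uniform_alpha_closed_form(self, rng):
        n, K = 12, 4
        labels = rng.integers(1, K + 1, n)
        alpha = Tensor(np.full((n, K), 1.0 / K))
        counts = np.bincount(labels, minlength=K + 1)[1:]
        g = counts[labels - 1] / n
        expected = (g.sum() / n) * np.log(K)
        assert np.isclose(classification_loss(alpha, labels).item(), expected, atol=1e-9)

    def test_wrong_confident_is_clamped_large(self):
        alpha = Tensor(np.array([[0.0, 1.0]]))
        val = classification_loss(alpha, np.array([1])).item()
        assert val > 10  # -log(eps), finite

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classification_loss(Tensor(np.full((2, 2), 0.5)), np.array([1, 3]))

    def test_gradients(self, rng):
        labels = np.array([1, 2, 3, 1, 2])

        def loss(logits):
            return classification_loss(logits.softmax(axis=-1), labels)

        check_grad(loss, [rng.standard_normal((5, 3))])


class TestComposites:
    def test_group_unsupervised_sum(self):
        parts = (Tensor(0.1), Tensor(0.2), Tensor(-0.5))
        assert np.isclose(compose_group_loss(parts, "unsupervised").item(), -0.2)

    def test_group_supervised_identity(self):
        assert compose_group_loss((Tensor(0.7),), "supervised").item() == 0.7

    def test_pgc_sum(self):
        parts = tuple(Tensor(float(v)) for v in (1, 2, 3, 4))
        assert compose_pgc_loss(parts).item() == 10.0
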