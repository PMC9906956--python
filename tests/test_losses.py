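"""Loss exactness against hand values and brute-force re-evaluations, plus
finite-difference gradient checks."""

import numpy as np
import pytest

from simscreen.autodiff import Tensor
from simscreen.losses import (SimilarityLossParams, TripletParams,
                              batch_similarity_loss, batch_triplet_loss,
                              combined_loss, logits_reconstruction_loss,
                              reconstruction_loss, similarity_loss,
                              triplet_loss)
from simscreen.tokenizer import PAD_ID


class TestReconstructionLoss:
    def test_perfect_onehot_is_zero(self):
        probs = np.eye(4)[None, :, :]          # [1, 4, 4], prob 1 at truth
        targets = np.array([[0, 1, 2, 3]])
        assert reconstruction_loss(probs, targets).item() == pytest.approx(
            0.0, abs=1e-9)

    def test_uniform_prediction_log_c(self):
        C, T = 5, 3
        probs = np.full((1, T, C), 1 / C)
        targets = np.array([[4, 2, 1]])
        loss = reconstruction_loss(probs, targets, reduction="mean")
        assert loss.item() == pytest.approx(np.log(C), rel=1e-9)
        total = reconstruction_loss(probs, targets, reduction="sum")
        assert total.item() == pytest.approx(T * np.log(C), rel=1e-9)

    def test_two_token_three_class_hand_example(self):
        # note class 0 is PAD and would be excluded; targets avoid it
        probs = np.array([[[0.7, 0.2, 0.1],
                           [0.1, 0.3, 0.6]]])
        targets = np.array([[1, 2]])
        expected = -(np.log(0.2) + np.log(0.6))
        assert reconstruction_loss(probs, targets).item() == pytest.approx(
            expected, rel=1e-9)

    def test_pad_positions_excluded(self):
        probs = np.array([[[0.1, 0.2, 0.3, 0.4],
                           [0.01, 0.01, 0.01, 0.97]]])
        targets = np.array([[3, PAD_ID]])  # second position is padding
        expected = -np.log(0.4)
        assert reconstruction_loss(probs, targets).item() == pytest.approx(
            expected, rel=1e-9)

    def test_zero_probability_clamped(self):
        probs = np.array([[[1.0, 0.0]]])
        targets = np.array([[1]])
        loss = reconstruction_loss(probs, targets).item()
        assert np.isfinite(loss) and loss > 20  # log(eps)

    def test_all_pad_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.ones((1, 2, 3)) / 3,
                                np.full((1, 2), PAD_ID))

    def test_logits_path_matches_probs_path(self, rng):
        logits = rng.normal(size=(2, 5, 7))
        targets = rng.integers(3, 7, size=(2, 5))
        probs = Tensor(logits).softmax(-1).data
        a = logits_reconstruction_loss(Tensor(logits), targets,
                                       reduction="sum").item()
        b = reconstruction_loss(probs, targets, reduction="sum").item()
        assert a == pytest.approx(b, rel=1e-9)


class TestTripletLoss:
    def test_anchor_equals_positive(self, rng):
        fA = rng.normal(size=8)
        fN = fA + 3.0
        loss = triplet_loss(fA, fA, fN, TripletParams(m=0.5))
        assert loss.item() == 0.0

    def test_hand_example_inactive_hinge(self):
        fA = np.zeros(2)
        fP = np.array([1.0, 0.0])     # ||fA-fP|| = 1
        fN = np.array([0.0, 2.0])     # ||fA-fN|| = 2
        assert triplet_loss(fA, fP, fN, TripletParams(m=0.5)).item() == 0.0

    def test_hand_example_active_hinge(self):
        fA = np.zeros(2)
        fP = np.array([2.0, 0.0])
        fN = np.array([0.0, 1.0])
        assert triplet_loss(fA, fP, fN, TripletParams(m=0.5)).item() == \
            pytest.approx(1.5, rel=1e-12)

    def test_bruteforce_1000_random_triplets(self, rng):
        for _ in range(1000):
            fA, fP, fN = rng.normal(size=(3, 6))
            m = float(rng.uniform(0, 2))
            got = triplet_loss(fA, fP, fN, TripletParams(m=m)).item()
            want = max(np.linalg.norm(fA - fP) - np.linalg.norm(fA - fN) + m,
                       0.0)
            assert got == pytest.approx(want, rel=1e-6, abs=1e-9)

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            TripletParams(m=-1)


class TestSimilarityLoss:
    def test_identical_latents_sim1(self, rng):
        f = rng.normal(size=8)
        assert similarity_loss(f, f, 1.0).item() == pytest.approx(0, abs=1e-9)

    def test_hand_example_zero(self):
        fA = np.zeros(4)
        fX = np.array([10.0, 0, 0, 0])
        params = SimilarityLossParams(a=20)
        assert similarity_loss(fA, fX, 0.5, params).item() == pytest.approx(
            0.0, abs=1e-12)

    def test_hand_example_three(self):
        fA = np.zeros(4)
        fX = np.array([5.0, 0, 0, 0])
        params = SimilarityLossParams(a=10)
        assert similarity_loss(fA, fX, 0.8, params).item() == pytest.approx(
            3.0, rel=1e-12)

    def test_bruteforce_1000_random_pairs(self, rng):
        for _ in range(1000):
            fA, fX = rng.normal(size=(2, 5)) * 5
            sim = float(rng.uniform(0, 1))
            a = float(rng.uniform(0.5, 30))
            got = similarity_loss(fA, fX, sim,
                                  SimilarityLossParams(a=a)).item()
            want = abs(a * (1 - sim) - np.linalg.norm(fA - fX))
            assert got == pytest.approx(want, rel=1e-6, abs=1e-9)

    def test_sim_out_of_range_rejected(self, rng):
        f = rng.normal(size=4)
        with pytest.raises(ValueError):
            similarity_loss(f, f, 1.2)
        with pytest.raises(ValueError):
            similarity_loss(f, f, -0.1)

    def test_invalid_scaling(self):
        with pytest.raises(ValueError):
            SimilarityLossParams(a=0)

    def test_zero_iff_distance_matches_target(self, rng):
        """Closed-form 2-point case: placing X at exactly a(1-sim) from A
        minimizes the loss to zero."""
        a, sim = 8.0, 0.25
        fA = rng.normal(size=3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        fX = fA + a * (1 - sim) * direction
        params = SimilarityLossParams(a=a)
        assert similarity_loss(fA, fX, sim, params).item() == pytest.approx(
            0.0, abs=1e-9)
        assert similarity_loss(fA, fX + 0.5 * direction, sim,
                               params).item() > 0.1


class TestBatchSimilarityLoss:
    def test_exact_placement_zero(self):
        a = 4.0
        latents = np.array([[0.0, 0], [2.0, 0], [4.0, 0]])
        sims = 1 - np.array([[0.0, 0.5, 1.0],
                             [0.5, 0.0, 0.5],
                             [1.0, 0.5, 0.0]])
        loss = batch_similarity_loss(latents, [0], sims,
                                     SimilarityLossParams(a=a))
        assert loss.item() == pytest.approx(0.0, abs=1e-9)

    def test_matches_hand_sum(self, rng):
        latents = rng.normal(size=(3, 4))
        sims = np.array([[1.0, 0.3, 0.6],
                         [0.3, 1.0, 0.2],
                         [0.6, 0.2, 1.0]])
        params = SimilarityLossParams(a=5.0)
        got = batch_similarity_loss(latents, [1], sims, params).item()
        want = np.mean([
            similarity_loss(latents[1], latents[0], 0.3, params).item(),
            similarity_loss(latents[1], latents[2], 0.2, params).item()])
        assert got == pytest.approx(want, rel=1e-9)

    def test_mean_over_multiple_anchors(self, rng):
        latents = rng.normal(size=(5, 3))
        sims = np.clip(rng.uniform(0, 1, (5, 5)), 0, 1)
        sims = (sims + sims.T) / 2
        np.fill_diagonal(sims, 1.0)
        params = SimilarityLossParams(a=3.0)
        got = batch_similarity_loss(latents, [0, 3], sims, params).item()
        terms = [similarity_loss(latents[a], latents[x], sims[a, x],
                                 params).item()
                 for a in (0, 3) for x in range(5) if x != a]
        assert got == pytest.approx(np.mean(terms), rel=1e-8)

    def test_order_invariance_of_non_anchors(self, rng):
        latents = rng.normal(size=(4, 3))
        sims = np.eye(4) * 0.5 + 0.5
        perm = [0, 3, 2, 1]
        a = batch_similarity_loss(latents, [0], sims).item()
        b = batch_similarity_loss(latents[perm], [0],
                                  sims[np.ix_(perm, perm)]).item()
        assert a == pytest.approx(b, rel=1e-9)

    def test_singleton_batch_rejected(self, rng):
        with pytest.raises(ValueError, match="pairs"):
            batch_similarity_loss(rng.normal(size=(1, 3)), [0],
                                  np.ones((1, 1)))


class TestBatchTripletLoss:
    def test_matches_bruteforce(self, rng):
        latents = rng.normal(size=(8, 4)) * 2
        sims = rng.uniform(0, 1, (8, 8))
        sims = (sims + sims.T) / 2
        np.fill_diagonal(sims, 1.0)
        params = TripletParams(m=1.0)
        anchors = [0, 2, 5]
        got = batch_triplet_loss(latents, anchors, sims, params).item()
        terms = []
        for a in anchors:
            pos = [j for j in range(8) if j != a and sims[a, j] >= 0.5]
            neg = [j for j in range(8) if j != a and sims[a, j] < 0.5]
            for p in pos:
                for n in neg:
                    terms.append(max(
                        np.linalg.norm(latents[a] - latents[p])
                        - np.linalg.norm(latents[a] - latents[n]) + 1.0, 0.0))
        assert got == pytest.approx(np.mean(terms), rel=1e-6)

    def test_no_valid_triplet_returns_zero(self, rng):
        latents = rng.normal(size=(4, 3))
        sims = np.ones((4, 4))  # everything similar -> no negatives
        assert batch_triplet_loss(latents, [0], sims).item() == 0.0


class TestCombinedLoss:
    def test_zero_shape_term(self):
        assert combined_loss(2.5, 0.0).item() == pytest.approx(2.5)

    def test_zero_weight_is_vanilla(self):
        assert combined_loss(2.5, 7.0, weight=0.0).item() == pytest.approx(2.5)

    def test_plain_sum(self):
        assert combined_loss(2.0, 3.0, weight=1.0).item() == pytest.approx(5.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            combined_loss(1.0, 1.0, weight=-0.5)


class TestGradients:
    """Finite-difference vs autodiff at 1e-4 relative on random inputs."""

    @staticmethod
    def _fd(build, tensor, eps=1e-6):
        grad = np.zeros_like(tensor.data)
        it = np.nditer(tensor.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = tensor.data[i]
            tensor.data[i] = orig + eps
            hi = build().item()
            tensor.data[i] = orig - eps
            lo = build().item()
            tensor.data[i] = orig
            grad[i] = (hi - lo) / (2 * eps)
        return grad

    def test_similarity_loss_gradient(self, rng):
        fA = Tensor(rng.normal(size=6), requires_grad=True)
        fX = Tensor(rng.normal(size=6), requires_grad=True)
        build = lambda: similarity_loss(fA, fX, 0.3,
                                        SimilarityLossParams(a=7))
        build().backward()
        np.testing.assert_allclose(fA.grad, self._fd(build, fA),
                                   rtol=1e-4, atol=1e-7)

    def test_triplet_loss_gradient(self, rng):
        fA = Tensor(rng.normal(size=5), requires_grad=True)
        fP = Tensor(rng.normal(size=5), requires_grad=True)
        fN = Tensor(rng.normal(size=5), requires_grad=True)
        build = lambda: triplet_loss(fA, fP, fN, TripletParams(m=3.0))
        assert build().item() > 0  # active hinge, differentiable region
        build().backward()
        for t in (fA, fP, fN):
            np.testing.assert_allclose(t.grad, self._fd(build, t),
                                       rtol=1e-4, atol=1e-7)

    def test_reconstruction_loss_gradient(self, rng):
        logits = Tensor(rng.normal(size=(2, 3, 5)), requires_grad=True)
        targets = rng.integers(1, 5, size=(2, 3))
        build = lambda: logits_reconstruction_loss(logits, targets)
        build().backward()
        np.testing.assert_allclose(logits.grad, self._fd(build, logits),
                                   rtol=1e-4, atol=1e-7)

    def test_batch_similarity_loss_gradient(self, rng):
        latents = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        sims = rng.uniform(0.1, 0.9, (4, 4))
        sims = (sims + sims.T) / 2
        np.fill_diagonal(sims, 1.0)
        build = lambda: batch_similarity_loss(latents, [0, 2], sims)
        build().backward()
        np.testing.assert_allclose(latents.grad, self._fd(build, latents),
                                   rtol=1e-4, atol=1e-7)


def test_all_losses_nonnegative_property(rng):
    for _ in range(200):
        fA, fP, fN = rng.normal(size=(3, 4)) * 3
        assert triplet_loss(fA, fP, fN,
                            TripletParams(m=float(rng.uniform(0, 2)))
                            ).item() >= 0
        assert similarity_loss(fA, fP, float(rng.uniform(0, 1)),
                               SimilarityLossParams(
                                   a=float(rng.uniform(0.1, 30)))
                               ).item() >= 0
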