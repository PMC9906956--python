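"""Evaluation protocol exactness: AUROC vs all-pairs oracle, retrieval
curves vs recount oracles, permutation nulls."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from simscreen.evaluation import (UndefinedAUROCError, auroc,
                                  choose_references, hit_identification_curve,
                                  ranking_histogram, threshold_auroc_protocol,
                                  topk_reproduction_curve)
from simscreen.search import EmbeddedLibrary


def allpairs_auroc(scores, labels):
    """Independent oracle: enumerate every positive-negative pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def lib_from(latents, prefix="m"):
    latents = np.asarray(latents, dtype=float)
    return EmbeddedLibrary(latents=latents,
                           mol_ids=[f"{prefix}{i:04d}"
                                    for i in range(len(latents))],
                           smiles=["C"] * len(latents))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert auroc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_four_point_worked_example(self):
        assert auroc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(
            0.75)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedAUROCError):
            auroc([1.0, 2.0], [1, 1])

    def test_matches_allpairs_oracle_with_ties(self, rng):
        for trial in range(30):
            n = int(rng.integers(10, 500))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # heavy ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert auroc(scores, labels) == pytest.approx(
                allpairs_auroc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, size=300)
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


class TestThresholdProtocol:
    def test_perfect_model_auroc_one(self, rng):
        """Ground truth defined from the latents themselves: distances are
        exactly a*(1-sim), so scores rank candidates perfectly."""
        n = 40
        X = rng.normal(size=(n, 6))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        sims = 1 - D / (1.05 * D.max())
        np.fill_diagonal(sims, 1.0)
        lib = lib_from(X)
        qs = np.quantile(sims[~np.eye(n, dtype=bool)], [0.6, 0.75, 0.9])
        report = threshold_auroc_protocol(lib, sims, range(n),
                                          thresholds=list(qs),
                                          min_sim=0.40)
        used = [t for t in report.thresholds if report.mean[t] is not None]
        assert used, "no threshold produced two classes"
        for t in used:
            assert report.mean[t] == pytest.approx(1.0, abs=1e-9)

    def test_shuffled_scores_near_half(self, rng):
        """Random embedding: mean AUROC within the permutation null band."""
        n = 200
        sims = rng.uniform(0.41, 0.99, size=(n, n))
        sims = (sims + sims.T) / 2
        np.fill_diagonal(sims, 1.0)
        lib = lib_from(rng.normal(size=(n, 16)))
        report = threshold_auroc_protocol(lib, sims, range(0, n, 4),
                                          thresholds=[0.7], min_sim=0.40)
        vals = report.mean[0.7], report.sd[0.7]
        assert abs(vals[0] - 0.5) < 3 * vals[1] / np.sqrt(50)

    def test_report_row_count(self, rng):
        n = 30
        sims = rng.uniform(0.5, 1.0, (n, n))
        sims = (sims + sims.T) / 2
        np.fill_diagonal(sims, 1.0)
        lib = lib_from(rng.normal(size=(n, 4)))
        thresholds = [0.55, 0.7, 0.85]
        report = threshold_auroc_protocol(lib, sims, [0, 5], thresholds)
        assert len(report.to_rows()) == len(thresholds)

    def test_single_class_references_skipped_and_counted(self, rng):
        n = 10
        sims = np.full((n, n), 0.9)  # all candidates positive at t=0.5
        np.fill_diagonal(sims, 1.0)
        lib = lib_from(rng.normal(size=(n, 4)))
        report = threshold_auroc_protocol(lib, sims, [0, 1],
                                          thresholds=[0.5])
        assert report.mean[0.5] is None
        assert len(report.skipped[0.5]) == 2


class TestTopkReproduction:
    def test_perfect_ranks_full_at_k(self, rng):
        n = 40
        X = rng.normal(size=(n, 6))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        sims = 1 - D / (D.max() + 1e-9)  # ground truth == latent geometry
        lib = lib_from(X)
        curve = topk_reproduction_curve(lib, sims, [0, 7], [10, 20], k=10)
        assert curve.mean[0] == pytest.approx(1.0)

    def test_full_grid_covers_library(self, rng):
        n = 50
        sims = rng.uniform(0, 1, (n, n))
        sims = (sims + sims.T) / 2
        np.fill_diagonal(sims, 1.0)
        lib = lib_from(rng.normal(size=(n, 4)))
        curve = topk_reproduction_curve(lib, sims, [3], [n - 1], k=10)
        assert curve.mean[-1] == pytest.approx(1.0)

    def test_random_embedding_hypergeometric_mean(self, rng):
        """E[found fraction] = N/(n-1) for an uninformative embedding."""
        n, N, k, n_refs = 1000, 100, 10, 20
        sims = rng.uniform(0, 1, (n, n))
        sims = (sims + sims.T) / 2
        np.fill_diagonal(sims, 1.0)
        lib = lib_from(rng.normal(size=(n, 8)))
        curve = topk_reproduction_curve(lib, sims, range(n_refs), [N], k=k)
        expected = N / (n - 1)
        # binomial-ish error over n_refs*k draws
        se = np.sqrt(expected * (1 - expected) / (n_refs * k))
        assert abs(curve.mean[0] - expected) < 4 * se

    def test_per_reference_curves_non_decreasing(self, rng):
        n = 60
        sims = rng.uniform(0, 1, (n, n))
        sims = (sims + sims.T) / 2
        np.fill_diagonal(sims, 1.0)
        lib = lib_from(rng.normal(size=(n, 4)))
        curve = topk_reproduction_curve(lib, sims, range(5),
                                        [5, 10, 20, 40, 59], k=5)
        assert (np.diff(curve.per_reference, axis=1) >= -1e-12).all()

    def test_k_too_large_rejected(self, rng):
        lib = lib_from(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            topk_reproduction_curve(lib, np.eye(5), [0], [3], k=5)


class TestHitIdentification:
    def _setup(self, rng, n=200):
        sims = rng.uniform(0, 1, (n, n))
        sims = (sims + sims.T) / 2
        np.fill_diagonal(sims, 1.0)
        lib = lib_from(rng.normal(size=(n, 8)))
        return lib, sims

    def test_matches_recount_oracle(self, rng):
        lib, sims = self._setup(rng)
        ref = 17
        recall = hit_identification_curve(lib, sims, ref, 0.5)
        # independent oracle: set intersection at every n
        X = lib.latents
        dist = np.sqrt(((X - X[ref]) ** 2).sum(-1))
        order = sorted((j for j in range(len(X)) if j != ref),
                       key=lambda j: (dist[j], lib.mol_ids[j]))
        similars = {j for j in range(len(X))
                    if j != ref and sims[ref, j] >= 0.5}
        for n in (1, 7, 50, 199):
            found = len(set(order[:n]) & similars)
            assert recall[n - 1] == pytest.approx(found / len(similars))

    def test_non_decreasing(self, rng):
        lib, sims = self._setup(rng, n=80)
        recall = hit_identification_curve(lib, sims, 3, 0.5)
        assert (np.diff(recall) >= -1e-12).all()

    def test_perfect_model_recall_one_at_similar_count(self, rng):
        n = 30
        X = rng.normal(size=(n, 5))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        sims = 1 - D / (D.max() + 1e-9)
        lib = lib_from(X)
        ref = 0
        n_similar = int((sims[ref] >= 0.5).sum() - 1)
        recall = hit_identification_curve(lib, sims, ref, 0.5)
        assert recall[n_similar - 1] == pytest.approx(1.0)

    def test_no_similars_raises_with_reference_name(self, rng):
        lib, sims = self._setup(rng, n=20)
        sims[:] = 0.0
        np.fill_diagonal(sims, 1.0)
        with pytest.raises(ValueError, match=lib.mol_ids[4]):
            hit_identification_curve(lib, sims, 4, 0.5)


class TestRankingHistogram:
    def test_counts_sum_to_top_n(self, rng):
        n = 100
        sims = rng.uniform(0, 1, (n, n))
        sims = (sims + sims.T) / 2
        np.fill_diagonal(sims, 1.0)
        lib = lib_from(rng.normal(size=(n, 4)))
        counts, edges = ranking_histogram(lib, sims, 0, top_n=50)
        assert counts.sum() == 50
        assert len(edges) == 21  # default 0.05 bins

    def test_matches_recount_oracle(self, rng):
        n = 60
        sims = rng.uniform(0, 1, (n, n))
        sims = (sims + sims.T) / 2
        np.fill_diagonal(sims, 1.0)
        lib = lib_from(rng.normal(size=(n, 4)))
        ref, top_n = 5, 25
        counts, edges = ranking_histogram(lib, sims, ref, top_n)
        X = lib.latents
        dist = np.sqrt(((X - X[ref]) ** 2).sum(-1))
        order = sorted((j for j in range(n) if j != ref),
                       key=lambda j: (dist[j], lib.mol_ids[j]))
        oracle, _ = np.histogram(sims[ref, order[:top_n]], bins=edges)
        np.testing.assert_array_equal(counts, oracle)

    def test_perfect_model_histogram_equals_truth(self, rng):
        n = 40
        X = rng.normal(size=(n, 5))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        sims = 1 - D / (D.max() + 1e-9)
        lib = lib_from(X)
        counts, edges = ranking_histogram(lib, sims, 0, top_n=20)
        truth = np.sort(sims[0, [j for j in range(n) if j != 0]])[-20:]
        oracle, _ = np.histogram(truth, bins=edges)
        np.testing.assert_array_equal(counts, oracle)


def test_choose_references_seeded(rng):
    a = choose_references(np.random.default_rng(5), range(100), 10)
    b = choose_references(np.random.default_rng(5), range(100), 10)
    np.testing.assert_array_equal(a, b)
    assert len(set(a.tolist())) == 10
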