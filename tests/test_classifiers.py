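from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import cdist

from cardioknn import (
    BlobSpec,
    LabeledDataset,
    NeighborSet,
    WeightVector,
    classify,
    correction_factors,
    dfwknn_weights,
    dswknn_weights,
    find_neighbors,
    gen_imbalanced_blobs,
    kernel_gram,
    knn_predict,
    solve_gram_weights,
    weighted_vote,
)
from cardioknn.synthetic import UCI_CLASS_COUNTS, UCI_CLASS_LABELS


def neighbor_set(distances, labels, query=None, k_dim=1):
    distances = np.asarray(distances, dtype=float)
    return NeighborSet(
        indices=np.arange(len(distances)),
        distances=distances,
        labels=np.asarray(labels),
        query=np.zeros(k_dim) if query is None else np.asarray(query, dtype=float),
    )


class TestFindNeighbors:
    def test_one_dimensional_example(self):
        train = LabeledDataset.from_arrays([[0.0], [10.0]], [1, 2])
        ns = find_neighbors([1.0], train, 1)
        assert ns.indices[0] == 0
        assert ns.distances[0] == pytest.approx(1.0)
        assert ns.labels[0] == 1

    def test_query_equal_to_training_row(self, rng):
        x = rng.standard_normal((10, 3))
        train = LabeledDataset.from_arrays(x, np.ones(10, dtype=int))
        ns = find_neighbors(x[4], train, 3)
        assert ns.indices[0] == 4
        assert ns.distances[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        x = rng.standard_normal((50, 5))
        train = LabeledDataset.from_arrays(x, rng.integers(1, 4, 50))
        for _ in range(10):
            q = rng.standard_normal(5)
            ns = find_neighbors(q, train, 7)
            oracle = cdist(q[None, :], x)[0]
            order = np.argsort(oracle, kind="stable")[:7]
            assert np.array_equal(ns.indices, order)
            np.testing.assert_allclose(ns.distances, oracle[order], atol=1e-9)

    def test_k_out_of_range_rejected(self):
        train = LabeledDataset.from_arrays([[0.0], [1.0]], [1, 2])
        with pytest.raises(ValueError):
            find_neighbors([0.0], train, 3)

    def test_missing_training_cells_rejected(self, small_masked):
        train = LabeledDataset(small_masked, np.array([1, 2]))
        with pytest.raises(ValueError, match="impute"):
            find_neighbors([0.0, 0.0], train, 1)


class TestKNNPredict:
    def test_majority(self):
        assert knn_predict(neighbor_set([1, 2, 3], [5, 5, 7])) == 5

    def test_tie_goes_to_nearest_member(self):
        assert knn_predict(neighbor_set([1, 2], [3, 9])) == 3
        assert knn_predict(neighbor_set([1, 2], [9, 3])) == 9

    @given(st.integers(0, 500))
    def test_matches_count_then_tiebreak_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(1, 5, size=rng.integers(1, 12))
        ns = neighbor_set(np.sort(rng.random(len(labels))), labels)
        counts = Counter(labels.tolist())
        top = max(counts.values())
        tied = {c for c, m in counts.items() if m == top}
        expected = next(int(l) for l in labels if l in tied)
        assert knn_predict(ns) == expected


class TestDSWKNNWeights:
    def test_printed_endpoints(self):
        w = dswknn_weights(neighbor_set([1.0, 2.0, 3.0], [1, 1, 2])).w
        np.testing.assert_allclose(w, [1.0, 0.5, 0.0])

    def test_all_equal_distances_degenerate_to_ones(self):
        w = dswknn_weights(neighbor_set([2.0, 2.0, 2.0], [1, 2, 1])).w
        np.testing.assert_allclose(w, [1.0, 1.0, 1.0])

    @given(st.integers(0, 500))
    def test_range_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        d = np.sort(rng.random(rng.integers(2, 10)))
        w = dswknn_weights(neighbor_set(d, np.ones(len(d), dtype=int))).w
        assert np.all((w >= 0) & (w <= 1))
        assert np.all(np.diff(w) <= 1e-12)  # non-increasing in distance
        if d[-1] > d[0]:
            assert w[0] == pytest.approx(1.0)
            assert w[-1] == pytest.approx(0.0)


class TestDFWKNNWeights:
    def test_single_neighbor_weight_is_one(self, rng):
        rows = rng.standard_normal((1, 4))
        ns = neighbor_set([1.0], [1], query=rng.standard_normal(4), k_dim=4)
        np.testing.assert_allclose(dfwknn_weights(ns, rows).w, [1.0])

    def test_symmetric_pair_splits_evenly(self):
        query = np.zeros(2)
        rows = np.array([[1.0, 2.0], [-1.0, -2.0]])  # x - x1 = -(x - x2)
        ns = neighbor_set([np.sqrt(5)] * 2, [1, 2], query=query, k_dim=2)
        np.testing.assert_allclose(dfwknn_weights(ns, rows).w, [0.5, 0.5], atol=1e-12)

    def test_matches_kkt_saddle_oracle(self, rng):
        for _ in range(20):
            k, d, eta = 6, 4, 0.01
            query = rng.standard_normal(d)
            rows = rng.standard_normal((k, d))
            ns = neighbor_set(np.sort(rng.random(k)), np.ones(k, dtype=int),
                              query=query, k_dim=d)
            w = dfwknn_weights(ns, rows, eta).w
            diffs = query[None, :] - rows
            g = diffs @ diffs.T
            g_reg = g + eta * np.trace(g) / k * np.eye(k)
            saddle = np.zeros((k + 1, k + 1))
            saddle[:k, :k] = g_reg
            saddle[:k, k] = 1.0
            saddle[k, :k] = 1.0
            rhs = np.zeros(k + 1)
            rhs[k] = 1.0
            expected = np.linalg.solve(saddle, rhs)[:k]
            np.testing.assert_allclose(w, expected, atol=1e-8)

    def test_weights_sum_to_one(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 9))
            rows = rng.standard_normal((k, 3))
            ns = neighbor_set(np.sort(rng.random(k)), np.ones(k, dtype=int),
                              query=rng.standard_normal(3), k_dim=3)
            assert dfwknn_weights(ns, rows).w.sum() == pytest.approx(1.0, abs=1e-10)

    def test_huge_eta_gives_uniform_weights(self, rng):
        k = 7
        rows = rng.standard_normal((k, 3))
        ns = neighbor_set(np.sort(rng.random(k)), np.ones(k, dtype=int),
                          query=rng.standard_normal(3), k_dim=3)
        w = dfwknn_weights(ns, rows, eta=1e6).w
        np.testing.assert_allclose(w, np.full(k, 1 / k), atol=1e-3)

    def test_query_equal_to_all_neighbors_uniform(self):
        query = np.ones(3)
        rows = np.tile(query, (4, 1))
        ns = neighbor_set(np.zeros(4), np.ones(4, dtype=int), query=query, k_dim=3)
        np.testing.assert_allclose(dfwknn_weights(ns, rows).w, np.full(4, 0.25))

    def test_negative_eta_rejected(self, rng):
        rows = rng.standard_normal((3, 2))
        ns = neighbor_set([1, 2, 3], [1, 1, 2], query=np.zeros(2), k_dim=2)
        with pytest.raises(ValueError):
            dfwknn_weights(ns, rows, eta=-0.1)


class TestKernelGram:
    def test_linear_kernel_equals_difference_gram(self, rng):
        query = rng.standard_normal(5)
        rows = rng.standard_normal((6, 5))
        ns = neighbor_set(np.sort(rng.random(6)), np.ones(6, dtype=int),
                          query=query, k_dim=5)
        ctx = kernel_gram(ns, rows, kernel="linear")
        diffs = query[None, :] - rows
        np.testing.assert_allclose(ctx.g, diffs @ diffs.T, atol=1e-10)

    def test_rbf_query_equal_to_neighbors_is_zero(self):
        query = np.array([1.0, 2.0])
        rows = np.tile(query, (4, 1))
        ns = neighbor_set(np.zeros(4), np.ones(4, dtype=int), query=query, k_dim=2)
        ctx = kernel_gram(ns, rows, kernel="rbf", bandwidth=1.0)
        np.testing.assert_allclose(ctx.g, np.zeros((4, 4)), atol=1e-12)

    def test_rbf_gram_positive_semidefinite(self, rng):
        query = rng.standard_normal(4)
        rows = rng.standard_normal((8, 4))
        ns = neighbor_set(np.sort(rng.random(8)), np.ones(8, dtype=int),
                          query=query, k_dim=4)
        ctx = kernel_gram(ns, rows, kernel="rbf")
        eigvals = np.linalg.eigvalsh(ctx.g)
        assert eigvals.min() >= -1e-10

    def test_unknown_kernel_rejected(self, rng):
        rows = rng.standard_normal((2, 2))
        ns = neighbor_set([1, 2], [1, 2], query=np.zeros(2), k_dim=2)
        with pytest.raises(ValueError, match="kernel"):
            kernel_gram(ns, rows, kernel="poly")


def table1_profile_dataset():
    """452 rows carrying the arrhythmia class inventory (features are dummies)."""
    labels = np.concatenate(
        [np.full(m, c) for c, m in zip(UCI_CLASS_LABELS, UCI_CLASS_COUNTS)]
    )
    return LabeledDataset.from_arrays(np.zeros((len(labels), 1)), labels)


class TestCorrectionFactors:
    def test_balanced_classes_all_gammas_equal(self):
        ds = LabeledDataset.from_arrays(np.zeros((30, 1)), [1] * 10 + [2] * 10 + [3] * 10)
        cf = correction_factors(ds)
        assert cf.lambda_ == 1
        assert len(set(round(g, 12) for g in cf.gamma.values())) == 1

    def test_arrhythmia_class_profile_hand_values(self):
        cf = correction_factors(table1_profile_dataset(), zeta=1e-4)
        assert cf.lambda_ == 7
        assert round(cf.gamma[1], 3) == 1.048  # dominant class, phi = 245
        assert round(cf.gamma[8], 3) == 2.621  # two-member class

    def test_single_class_gamma_near_one(self):
        ds = LabeledDataset.from_arrays(np.zeros((50, 1)), [4] * 50)
        cf = correction_factors(ds)
        assert cf.gamma[4] == pytest.approx(1.0, abs=1e-4)

    def test_gamma_strictly_decreasing_in_class_count(self):
        cf = correction_factors(table1_profile_dataset())
        pairs = sorted(cf.phi.items(), key=lambda kv: kv[1])
        gammas = [cf.gamma[c] for c, _ in pairs]
        counts = [m for _, m in pairs]
        for i in range(len(counts) - 1):
            if counts[i] < counts[i + 1]:
                assert gammas[i] > gammas[i + 1]

    def test_invalid_inputs_rejected(self):
        ds = table1_profile_dataset()
        with pytest.raises(ValueError):
            correction_factors(ds, zeta=0.0)
        with pytest.raises(ValueError):
            correction_factors(LabeledDataset.from_arrays(np.zeros((2, 1)), None))


class TestWeightedVote:
    def test_plain_weighted_majority(self):
        ns = neighbor_set([1.0, 2.0], [1, 2])
        assert weighted_vote(ns, WeightVector(np.array([0.6, 0.4]))) == 1

    def test_gamma_flips_the_vote(self):
        ns = neighbor_set([1.0, 2.0], [1, 2])
        cf = correction_factors(
            LabeledDataset.from_arrays(np.zeros((3, 1)), [1, 1, 2])
        )
        cf.gamma = {1: 0.5, 2: 1.0}  # scores 0.30 vs 0.40
        assert weighted_vote(ns, WeightVector(np.array([0.6, 0.4])), cf) == 2

    @given(st.integers(0, 500))
    def test_matches_per_class_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 10))
        labels = rng.integers(1, 4, k)
        w = rng.standard_normal(k)
        ns = neighbor_set(np.sort(rng.random(k)), labels)
        scores = {}
        for lab, wi in zip(labels.tolist(), w):
            scores[lab] = scores.get(lab, 0.0) + wi
        top = max(scores.values())
        tied = {c for c, s in scores.items() if s == top}
        expected = next(int(l) for l in labels if l in tied)
        assert weighted_vote(ns, WeightVector(w)) == expected

    def test_missing_gamma_for_label_rejected(self):
        ns = neighbor_set([1.0], [9])
        cf = correction_factors(LabeledDataset.from_arrays(np.zeros((2, 1)), [1, 1]))
        with pytest.raises(ValueError, match="class 9"):
            weighted_vote(ns, WeightVector(np.array([1.0])), cf)


class TestClassify:
    def test_k1_all_methods_agree_with_nearest_neighbor(self, rng):
        train = gen_imbalanced_blobs(BlobSpec([20, 10, 5], dim=3, separation=3.0, seed=2))
        queries = rng.standard_normal((15, 3))
        reference = None
        for method in ("knn", "dswknn", "dfwknn", "kdfwknn", "mkdfwknn"):
            pred = classify(train, queries, method, k=1)
            if reference is None:
                reference = pred
            assert np.array_equal(pred, reference)

    def test_kdf_linear_kernel_equals_dfwknn(self, rng):
        train = LabeledDataset.from_arrays(
            rng.standard_normal((60, 4)), rng.integers(1, 4, 60)
        )
        queries = rng.standard_normal((40, 4))
        df = classify(train, queries, "dfwknn", k=9)
        kdf = classify(train, queries, "kdfwknn", k=9, kernel="linear")
        assert np.array_equal(df, kdf)

    def test_separated_blobs_classified_perfectly(self):
        train = gen_imbalanced_blobs(BlobSpec([40, 40], dim=2, separation=10.0, seed=3))
        test = gen_imbalanced_blobs(BlobSpec([25, 25], dim=2, separation=10.0, seed=4))
        for method in ("knn", "dswknn", "dfwknn", "kdfwknn", "mkdfwknn"):
            pred = classify(train, test.features.values, method, k=5)
            assert np.array_equal(pred, test.labels), method

    def test_mkdf_equals_kdf_on_balanced_training(self, rng):
        train = gen_imbalanced_blobs(BlobSpec([30, 30, 30], dim=4, separation=2.0, seed=5))
        queries = rng.standard_normal((50, 4)) * 2
        kdf = classify(train, queries, "kdfwknn", k=11)
        mkdf = classify(train, queries, "mkdfwknn", k=11)
        assert np.array_equal(kdf, mkdf)

    def test_deterministic_given_inputs(self, rng):
        train = gen_imbalanced_blobs(BlobSpec([25, 15], dim=3, separation=1.0, seed=6))
        queries = rng.standard_normal((20, 3))
        a = classify(train, queries, "mkdfwknn", k=7)
        b = classify(train, queries, "mkdfwknn", k=7)
        assert np.array_equal(a, b)

    def test_standardize_changes_scale_sensitivity(self):
        # one huge-scale noise column dominates raw distances
        rng = np.random.default_rng(11)
        x = np.c_[np.r_[np.zeros(20), np.ones(20)], rng.standard_normal(40) * 1e4]
        train = LabeledDataset.from_arrays(x, np.r_[np.ones(20), np.full(20, 2)].astype(int))
        queries = np.array([[0.0, 0.0], [1.0, 0.0]])
        pred = classify(train, queries, "knn", k=5, standardize=True)
        assert np.array_equal(pred, [1, 2])

    def test_invalid_method_rejected(self, rng):
        train = LabeledDataset.from_arrays(rng.standard_normal((5, 2)), [1, 1, 2, 2, 1])
        with pytest.raises(ValueError, match="valid"):
            classify(train, np.zeros((1, 2)), "svm", k=3)
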