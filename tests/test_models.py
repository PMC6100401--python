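import logging

import numpy as np
import pytest

from scfp.models import (ConfusionMatrix, ExtremeEntropyMachine,
                         HyperparameterGrid, ModelSpec, balanced_accuracy,
                         cross_validate, gram_matrix, grid_search, rbf_kernel,
                         sorensen_kernel, stratified_kfold, tanimoto_kernel)


class TestBalancedAccuracy:
    @pytest.mark.parametrize(
        "cm, expected",
        [
            (ConfusionMatrix(TP=10, FP=0, TN=10, FN=0), 1.0),
            (ConfusionMatrix(TP=0, FP=0, TN=10, FN=10), 0.5),
            (ConfusionMatrix(TP=8, FP=1, TN=3, FN=2), 0.775),
            (ConfusionMatrix(TP=5, FP=5, TN=0, FN=0), 0.5),
        ],
    )
    def test_hand_values(self, cm, expected):
        assert balanced_accuracy(cm) == pytest.approx(expected)

    def test_absent_class_raises(self):
        with pytest.raises(ValueError, match="no positive"):
            balanced_accuracy(ConfusionMatrix(TP=0, FP=1, TN=9, FN=0))
        with pytest.raises(ValueError, match="no negative"):
            balanced_accuracy(ConfusionMatrix(TP=9, FP=0, TN=0, FN=1))

    def test_invariant_to_class_rebalancing(self):
        base = ConfusionMatrix(TP=8, FP=1, TN=3, FN=2)
        scaled = ConfusionMatrix(TP=24, FP=1, TN=3, FN=6)  # positives x3
        assert balanced_accuracy(base) == pytest.approx(balanced_accuracy(scaled))


class TestKernels:
    def test_tanimoto_hand_values(self):
        x, y = np.array([1, 1, 0]), np.array([0, 1, 1])
        assert tanimoto_kernel(x, x) == 1.0
        assert tanimoto_kernel(x, y) == pytest.approx(1 / 3)
        assert tanimoto_kernel(np.array([1, 0]), np.array([0, 1])) == 0.0
        assert tanimoto_kernel(np.zeros(3), np.zeros(3)) == 1.0  # 0/0 convention

    def test_sorensen_hand_values(self):
        x, y = np.array([1, 1, 0]), np.array([0, 1, 1])
        assert sorensen_kernel(x, x) == 1.0
        assert sorensen_kernel(x, y) == pytest.approx(0.5)
        assert sorensen_kernel(np.array([1, 0]), np.array([0, 1])) == 0.0
        assert sorensen_kernel(np.zeros(3), np.zeros(3)) == 1.0

    def test_rbf_closed_forms(self):
        x = np.array([1.0, 0.0])
        assert rbf_kernel(x, x, gamma=2.0) == 1.0
        assert rbf_kernel(x, np.array([0.0, 0.0]), gamma=1.0) == pytest.approx(np.exp(-1))
        assert rbf_kernel(x, np.array([0.0, 1.0]), gamma=1e-12) == pytest.approx(1.0)

    def test_length_mismatch_raises(self):
        for kern in (tanimoto_kernel, sorensen_kernel):
            with pytest.raises(ValueError):
                kern(np.ones(3), np.ones(4))

    def test_gram_matches_scalar_kernel_and_is_valid(self):
        rng = np.random.default_rng(0)
        X = (rng.random((20, 8)) < 0.5).astype(float)
        for name, scalar in (("tanimoto", tanimoto_kernel),
                             ("sorensen", sorensen_kernel)):
            G = gram_matrix(X, X, name)
            assert np.allclose(G, G.T)
            assert np.allclose(np.diag(G), 1.0)
            assert G.min() >= 0 and G.max() <= 1
            for a in range(0, 20, 7):
                for b in range(0, 20, 5):
                    assert G[a, b] == pytest.approx(scalar(X[a], X[b]))

    def test_rbf_gram_positive_semidefinite(self):
        rng = np.random.default_rng(1)
        X = rng.random((15, 4))
        G = gram_matrix(X, X, "rbf", gamma=0.7)
        assert np.linalg.eigvalsh(G).min() > -1e-9

    def test_identical_vectors_all_ones(self):
        X = np.ones((2, 5))
        assert np.allclose(gram_matrix(X, X, "tanimoto"), 1.0)


class TestEEM:
    def test_separable_gaussian_clouds(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, size=(100, 2))
        b = rng.normal(5.0, 1.0, size=(100, 2))
        X = np.vstack([a, b])
        y = np.r_[np.zeros(100, dtype=int), np.ones(100, dtype=int)]
        eem = ExtremeEntropyMachine(h=1.0, C=100.0, base="euclidean",
                                    random_state=0).fit(X, y)
        cm = ConfusionMatrix.from_labels(y, eem.predict(X))
        assert balanced_accuracy(cm) >= 0.99

    def test_null_labels_chance_level(self, null_fixture):
        X, y = null_fixture
        cv = cross_validate(X, y, ModelSpec("eem", (("C", 1000.0), ("h", 0.5))),
                            seed=42)
        assert 0.4 <= cv.mean_bac <= 0.6

    def test_seed_determinism(self, separable_fixture):
        X, y = separable_fixture
        preds = [ExtremeEntropyMachine(h=0.5, C=100.0, random_state=9)
                 .fit(X, y).predict(X) for _ in range(2)]
        assert np.array_equal(preds[0], preds[1])

    def test_row_permutation_permutes_predictions(self, separable_fixture):
        X, y = separable_fixture
        eem = ExtremeEntropyMachine(h=0.5, C=100.0, random_state=3).fit(X, y)
        perm = np.random.default_rng(4).permutation(len(X))
        assert np.array_equal(eem.predict(X[perm]), eem.predict(X)[perm])

    def test_single_class_rejected(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError, match="2 classes"):
            ExtremeEntropyMachine().fit(X, np.zeros(10, dtype=int))

    def test_zero_C_survives_degenerate_covariance(self):
        # constant features make the covariance singular; ridge must handle it
        X = np.repeat(np.array([[1.0, 0.0], [0.0, 1.0]]), 10, axis=0)
        y = np.r_[np.ones(10, dtype=int), np.zeros(10, dtype=int)]
        eem = ExtremeEntropyMachine(h=0.5, C=0.0, base="euclidean",
                                    random_state=0).fit(X, y)
        assert np.all(np.isfinite(eem.w_))
        assert np.array_equal(eem.predict(X), y)


class TestNaiveBayesAndSVM:
    def test_informative_bit_dominates(self):
        rng = np.random.default_rng(2)
        X = (rng.random((60, 10)) < 0.5).astype(float)
        y = X[:, 0].astype(int)  # bit 0 perfectly correlated with the label
        model = ModelSpec("nb", (("alpha", 0.01),)).build()
        assert np.array_equal(model.fit(X, y).predict(X), y)

    def test_constant_bits_predict_majority(self):
        X = np.ones((30, 4))
        y = np.r_[np.ones(20, dtype=int), np.zeros(10, dtype=int)]
        preds = ModelSpec("nb", (("alpha", 0.5),)).build().fit(X, y).predict(X)
        assert np.all(preds == 1)

    def test_huge_alpha_washes_out_likelihoods(self):
        rng = np.random.default_rng(3)
        X = (rng.random((40, 6)) < 0.5).astype(float)
        y = np.r_[np.ones(25, dtype=int), np.zeros(15, dtype=int)]
        from scfp.models import BernoulliNaiveBayes
        preds = BernoulliNaiveBayes(alpha=1e9).fit(X, y).predict(X)
        assert np.all(preds == 1)

    def test_separable_svm_perfect_training_accuracy(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [1.0, 1.0], [0.9, 1.0]])
        y = np.array([0, 0, 1, 1])
        model = ModelSpec("rbf_svm", (("C", 1e6), ("gamma", 1.0))).build()
        assert np.array_equal(model.fit(X, y).predict(X), y)

    def test_invalid_hyperparameters_rejected(self):
        for spec in (ModelSpec("nb", (("alpha", 0.0),)),
                     ModelSpec("tan_svm", (("C", -1.0),)),
                     ModelSpec("rbf_svm", (("C", 1.0), ("gamma", 0.0)))):
            with pytest.raises(ValueError):
                spec.build()


class TestCrossValidation:
    def test_stratified_exact_division(self):
        y = np.r_[np.ones(10, dtype=int), np.zeros(10, dtype=int)]
        for _, te in stratified_kfold(y, k=5, seed=1):
            assert y[te].sum() == 2 and (1 - y[te]).sum() == 2

    def test_stratified_remainder_rule(self):
        y = np.r_[np.ones(11, dtype=int), np.zeros(10, dtype=int)]
        pos_counts = sorted(int(y[te].sum()) for _, te in stratified_kfold(y, 5, 1))
        assert pos_counts == [2, 2, 2, 2, 3]

    def test_folds_partition_index_set(self):
        y = np.r_[np.ones(23, dtype=int), np.zeros(17, dtype=int)]
        folds = stratified_kfold(y, k=5, seed=7)
        test_sets = [set(te.tolist()) for _, te in folds]
        assert set().union(*test_sets) == set(range(40))
        for a in range(5):
            assert set(folds[a][0].tolist()) == set(range(40)) - test_sets[a]
            for b in range(a + 1, 5):
                assert not (test_sets[a] & test_sets[b])

    def test_class_smaller_than_k_raises(self):
        y = np.r_[np.ones(3, dtype=int), np.zeros(20, dtype=int)]
        with pytest.raises(ValueError, match="class"):
            stratified_kfold(y, k=5, seed=0)

    def test_cv_separable_and_null(self, separable_fixture, null_fixture):
        X, y = separable_fixture
        cv = cross_validate(X, y, ModelSpec("tan_svm", (("C", 1.0),)), seed=42)
        assert cv.mean_bac >= 0.95
        assert len(cv.folds) == 5
        assert sum(f.confusion.n for f in cv.folds) == len(y)
        Xn, yn = null_fixture
        cvn = cross_validate(Xn, yn, ModelSpec("tan_svm", (("C", 1.0),)), seed=42)
        assert 0.4 <= cvn.mean_bac <= 0.6

    def test_cv_result_summary_mentions_bac(self, separable_fixture):
        X, y = separable_fixture
        cv = cross_validate(X, y, ModelSpec("nb", (("alpha", 1.0),)), seed=42)
        assert "mean BAC" in cv.summary()


class TestGridSearch:
    def test_declared_grid_sizes(self):
        grid = HyperparameterGrid()
        assert grid.n_configurations() == 121
        specs = list(grid.configurations())
        assert len(specs) == 121
        by_model = {m: sum(s.name == m for s in specs)
                    for m in ("nb", "eem", "tan_svm", "rbf_svm")}
        assert by_model == {"nb": 5, "eem": 16, "tan_svm": 10, "rbf_svm": 90}

    def test_restricted_grids(self):
        assert HyperparameterGrid(models=("nb",)).n_configurations() == 5
        assert HyperparameterGrid(models=("eem",)).n_configurations() == 16

    def test_best_is_argmax_and_count_logged(self, separable_fixture, caplog):
        X, y = separable_fixture
        grid = HyperparameterGrid(models=("nb",))
        with caplog.at_level(logging.INFO, logger="scfp.models"):
            res = grid_search(X, y, grid, seed=42)
        assert "5 configurations" in caplog.text
        assert len(res.table) == 5
        assert res.best_cv.mean_bac == pytest.approx(res.table["mean_bac"].max())
        assert res.best_cv.mean_bac >= max(
            r for r in res.table["mean_bac"])

    def test_tie_breaking_prefers_simpler_model(self, separable_fixture):
        # on a cleanly separable set many configurations tie at BAC 1.0;
        # the simplest family enumerated first must win
        X, y = separable_fixture
        grid = HyperparameterGrid(models=("nb", "eem", "tan_svm"))
        res = grid_search(X, y, grid, seed=42)
        tied = res.table[res.table["mean_bac"] >= res.best_cv.mean_bac]
        first = tied.iloc[0]
        assert res.best_spec.name == first["model"]
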