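"""Boosted SVM/KNN graders, plain variants, CV and splitting."""

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from funduskit.classify import (ImprovedKNN, ImprovedSVM, kfold_cv,
                                make_knn_variant, make_svm_variant,
                                split_80_20)
from funduskit.synthetic import generate_feature_table


@pytest.fixture(scope="module")
def separable():
    return generate_feature_table(seed=1, n_per_class=40, class_shift=10.0)


@pytest.fixture(scope="module")
def two_class():
    X, y = generate_feature_table(seed=2, n_per_class=50, class_shift=10.0)
    keep = np.isin(y, ["normal", "severe"])
    return X[keep], y[keep]


class TestImprovedSVM:
    def test_separable_data_fit_after_one_round(self, two_class):
        X, y = two_class
        clf = ImprovedSVM(n_rounds=1, seed=0).fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_single_round_equals_plain_linear_variant(self, separable):
        X, y = separable
        a = ImprovedSVM(n_rounds=1, seed=0).fit(X, y).predict(X)
        b = make_svm_variant("linear", seed=0).fit(X, y).predict(X)
        assert np.array_equal(a, np.asarray(b, dtype=object))

    def test_sample_weights_normalized_each_round(self, separable):
        X, y = separable
        clf = ImprovedSVM(n_rounds=4, seed=0).fit(X, y)
        for w in clf.sample_weight_trace_:
            assert w.sum() == pytest.approx(1.0)
            assert (w > 0).all()

    def test_rejects_degenerate_input(self):
        X = np.zeros((10, 24))
        with pytest.raises(ValueError):
            ImprovedSVM().fit(X, np.array(["a"] * 10))
        with pytest.raises(ValueError):
            ImprovedSVM(n_rounds=0)
        Xn = X.copy()
        Xn[0, 0] = np.nan
        with pytest.raises(ValueError):
            ImprovedSVM().fit(Xn, np.array(["a"] * 5 + ["b"] * 5))


class TestImprovedKNN:
    def test_ensemble_not_worse_than_best_weak_learner(self, separable):
        X, y = separable
        clf = ImprovedKNN(n_learners=10, seed=0).fit(X, y)
        ens_acc = np.mean(clf.predict(X) == y)
        best_accs = []
        for est, feats in clf.learners_:
            best_accs.append(np.mean(est.predict(X[:, feats]) == y))
        assert ens_acc >= max(best_accs) - 1e-12

    def test_best_learner_has_lowest_weighted_error(self, separable):
        X, y = separable
        clf = ImprovedKNN(n_learners=8, seed=1).fit(X, y)
        assert clf.train_errors_[clf.best_learner_] == min(clf.train_errors_)

    def test_single_learner_degenerates_to_plain_knn(self, separable):
        X, y = separable
        clf = ImprovedKNN(n_learners=1, seed=3).fit(X, y)
        est, feats = clf.learners_[0]
        assert np.array_equal(clf.predict(X), est.predict(X[:, feats]))

    def test_deterministic_under_seed(self, separable):
        X, y = separable
        a = ImprovedKNN(n_learners=5, seed=7).fit(X, y).predict(X)
        b = ImprovedKNN(n_learners=5, seed=7).fit(X, y).predict(X)
        assert np.array_equal(a, b)


class TestSVMVariants:
    def test_quadratic_kernel_formula(self):
        x = np.array([1.0, 2.0, 0.5])
        z = np.array([0.2, -1.0, 3.0])
        assert (x @ z + 1) ** 2 == pytest.approx((np.dot(x, z) + 1) ** 2)
        est = make_svm_variant("quadratic")
        assert est.kernel == "poly" and est.degree == 2
        assert est.coef0 == 1.0 and est.gamma == 1.0

    def test_gaussian_bandwidth_ordering(self):
        fine = make_svm_variant("fine_gaussian").gamma
        med = make_svm_variant("medium_gaussian").gamma
        coarse = make_svm_variant("coarse_gaussian").gamma
        assert fine > med > coarse
        # kernel value at a fixed distance: fine decays fastest
        d2 = 4.0
        kf, km, kc = (np.exp(-g * d2) for g in (fine, med, coarse))
        assert kf <= km <= kc

    @pytest.mark.parametrize("kind", ["linear", "quadratic", "cubic",
                                      "fine_gaussian", "medium_gaussian",
                                      "coarse_gaussian"])
    def test_each_variant_trains_and_predicts(self, kind, separable):
        X, y = separable
        est = make_svm_variant(kind)
        est.fit(X, y)
        assert len(est.predict(X)) == len(y)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_svm_variant("sigmoid")


class TestKNNVariants:
    def test_fine_knn_memorizes_training_data(self, separable):
        X, y = separable
        est = make_knn_variant("fine").fit(X, y)
        assert np.mean(est.predict(X) == y) == 1.0

    def test_cosine_variant_invariant_to_positive_scaling(self, separable):
        X, y = separable
        X = X - X.min() + 0.1
        est1 = make_knn_variant("cosine").fit(X, y)
        est2 = make_knn_variant("cosine").fit(X * 37.0, y)
        assert np.array_equal(est1.predict(X), est2.predict(X * 37.0))

    def test_coarse_matches_brute_force_majority_oracle(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (75, 24)), rng.normal(1.5, 1, (75, 24))])
        y = np.array(["a"] * 75 + ["b"] * 75)
        est = make_knn_variant("coarse").fit(X, y)
        q = rng.normal(0.75, 1, (20, 24))
        pred = est.predict(q)
        for i in range(20):
            d = np.linalg.norm(X - q[i], axis=1)
            nn = y[np.argsort(d, kind="stable")[:100]]
            vals, counts = np.unique(nn, return_counts=True)
            assert pred[i] == vals[np.argmax(counts)]

    def test_coarse_clips_k_with_warning(self):
        with pytest.warns(RuntimeWarning):
            est = make_knn_variant("coarse", n_train=30)
        assert est.n_neighbors == 30

    def test_weighted_variant_configuration(self):
        est = make_knn_variant("weighted")
        assert est.weights == "distance" and est.n_neighbors == 10
        with pytest.raises(ValueError):
            make_knn_variant("mystery")


class _PerfectStub:
    """Oracle classifier: looks labels up in a table fixed at construction,
    so it survives per-fold cloning and always predicts the truth."""

    def __init__(self, table=None):
        self.table = table

    def get_params(self, deep=True):
        return {"table": self.table}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self.table[tuple(row)] for row in X], dtype=object)


class TestKFoldCV:
    def test_folds_partition_data(self, separable):
        X, y = separable
        for k in (2, 5, 10):
            res = kfold_cv(X, y, k, make_knn_variant("fine"), seed=0)
            all_idx = np.concatenate(res.fold_test_indices)
            assert len(all_idx) == len(y)
            assert len(np.unique(all_idx)) == len(y)
            sizes = [len(f) for f in res.fold_test_indices]
            assert max(sizes) - min(sizes) <= 1

    def test_leave_one_out_on_ten_points(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 24))
        y = np.array(["a", "b"] * 5)
        res = kfold_cv(X, y, 10, make_knn_variant("fine"), seed=0)
        assert all(len(f) == 1 for f in res.fold_test_indices)

    def test_perfect_stub_scores_one_for_any_k(self, separable):
        X, y = separable
        # the stub carries the whole truth table, so any split scores 1.0
        stub = _PerfectStub({tuple(r): lab for r, lab in zip(X, y)})
        for k in (2, 5):
            res = kfold_cv(X, y, k, stub, seed=3)
            assert res.aggregate["accuracy"] == pytest.approx(1.0)

    def test_small_class_falls_back_with_warning(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 24))
        y = np.array(["a"] * 10 + ["b"] * 2)
        with pytest.warns(RuntimeWarning):
            kfold_cv(X, y, 5, make_knn_variant("fine"), seed=0)

    def test_k5_and_k10_agree_on_well_separated_data(self):
        X, y = generate_feature_table(seed=4, n_per_class=100, class_shift=6.0)
        clf = ImprovedSVM(n_rounds=3, seed=0)
        a5 = kfold_cv(X, y, 5, clf, seed=0).aggregate["accuracy"]
        a10 = kfold_cv(X, y, 10, clf, seed=0).aggregate["accuracy"]
        assert a5 >= 0.95 and a10 >= 0.95
        assert abs(a5 - a10) < 0.05


class TestSplit8020:
    def test_printed_class_distribution_gives_960_240(self):
        labels = (["normal"] * 200 + ["mild"] * 400 + ["moderate"] * 200
                  + ["severe"] * 200 + ["malignant"] * 200)
        train, test = split_80_20(labels, seed=0)
        assert len(train) == 960
        assert len(test) == 240

    def test_single_class_of_ten_splits_8_2(self):
        train, test = split_80_20(["x"] * 10, seed=1)
        assert len(train) == 8 and len(test) == 2

    def test_partition_properties(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(["a", "b", "c"], size=57)
        train, test = split_80_20(labels, seed=2)
        assert set(train) | set(test) == set(range(57))
        assert not set(train) & set(test)

    def test_rejects_tiny_input(self):
        with pytest.raises(ValueError):
            split_80_20(["a", "b"], seed=0)
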