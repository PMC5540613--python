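import numpy as np
import pandas as pd
import pytest

from propsig.classify import (
    ClassifierSpec,
    knn_classify,
    map_labels,
    run_problem,
    stratified_repeated_cv,
    summarize_boxstats,
    svm_classify,
)
from propsig.errors import ConfigurationError


def two_clusters(rng, n=50, sep=10.0, dim=3):
    a = rng.normal(0, 1, (n, dim))
    b = rng.normal(sep, 1, (n, dim))
    X = np.vstack([a, b])
    y = np.array(["A"] * n + ["B"] * n)
    return X, y


class TestKNN:
    def test_unanimous_neighbourhood(self, rng):
        X, y = two_clusters(rng)
        pred = knn_classify(X, y, X[[0]], k=10)
        assert pred[0] == "A"

    def test_separated_clusters_perfect_cubic(self, rng):
        X, y = two_clusters(rng)
        test = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(10, 1, (20, 3))])
        truth = np.array(["A"] * 20 + ["B"] * 20)
        pred = knn_classify(X, y, test, k=10, metric="cubic")
        assert np.array_equal(pred, truth)

    def test_direction_separated_clusters_perfect_cosine(self, rng):
        # cosine distance separates by direction, not magnitude
        a = rng.normal([8, 0, 0], 0.5, (40, 3))
        b = rng.normal([0, 8, 0], 0.5, (40, 3))
        X = np.vstack([a, b])
        y = np.array(["A"] * 40 + ["B"] * 40)
        test = np.vstack([rng.normal([8, 0, 0], 0.5, (15, 3)), rng.normal([0, 8, 0], 0.5, (15, 3))])
        truth = np.array(["A"] * 15 + ["B"] * 15)
        pred = knn_classify(X, y, test, k=10, metric="cosine")
        assert np.array_equal(pred, truth)

    def test_cosine_scale_invariance(self, rng):
        X, y = two_clusters(rng)
        test = rng.normal(5, 3, (15, 3))
        p1 = knn_classify(X, y, test, metric="cosine")
        p2 = knn_classify(X, y, 5.0 * test, metric="cosine")
        assert np.array_equal(p1, p2)

    def test_cubic_matches_euclidean_ordering_in_1d(self, rng):
        # on one feature, |.|^3 summed over a single axis is a monotone
        # transform of euclidean distance, so orderings coincide
        X = rng.normal(0, 1, (40, 1))
        y = np.where(X[:, 0] > 0, "pos", "neg")
        test = rng.normal(0, 1, (25, 1))
        cubic = knn_classify(X, y, test, k=5, metric="cubic")
        d = np.abs(test - X[:, 0][None, :])
        euclid = []
        for row in d:
            idx = np.argsort(row, kind="stable")[:5]
            lab, cnt = np.unique(y[idx], return_counts=True)
            win = lab[cnt == cnt.max()]
            euclid.append(win[0] if len(win) == 1 else y[idx[0]])
        assert np.array_equal(cubic, np.array(euclid))

    def test_k_exceeding_train_rejected(self, rng):
        X, y = two_clusters(rng, n=4)
        with pytest.raises(ConfigurationError):
            knn_classify(X, y, X, k=10)


class TestSVM:
    def test_separable_clusters_perfect(self, rng):
        X, y = two_clusters(rng)
        # standardize as the CV harness does
        Xs = (X - X.mean(0)) / X.std(0)
        pred = svm_classify(Xs[::2], y[::2], Xs[1::2])
        assert np.mean(pred == y[1::2]) == 1.0

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ConfigurationError):
            svm_classify(X, np.array(["A"] * 10), X)

    def test_nu_variant_runs(self, rng):
        X, y = two_clusters(rng)
        pred = svm_classify(X, y, X[:5], variant="nu")
        assert len(pred) == 5


class TestBoxStats:
    def test_percentile_formula(self):
        out = summarize_boxstats(np.arange(1, 101))
        assert out["q1"] == pytest.approx(25.75)
        assert out["q3"] == pytest.approx(75.25)
        assert len(out["outliers"]) == 0

    def test_outlier_rule(self):
        out = summarize_boxstats(np.array([0.0, 0.0, 0.0, 0.0, 10.0]))
        assert list(out["outliers"]) == [10.0]

    def test_constant_vector_flags_any_deviation(self):
        out = summarize_boxstats(np.array([1.0] * 10 + [1.001]))
        assert list(out["outliers"]) == [1.001]

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            summarize_boxstats(np.array([]))


class TestRepeatedCV:
    def test_fold_count_and_perfect_separation(self, rng):
        X, y = two_clusters(rng, n=13)
        rep = stratified_repeated_cv(X, y, ClassifierSpec(), seed=7)
        assert len(rep.fold_accuracies) == 200
        assert rep.mean == 1.0
        assert rep.sd == 0.0

    def test_stratified_proportions_within_one_sample(self, rng):
        from sklearn.model_selection import RepeatedStratifiedKFold

        y = np.array(["A"] * 13 + ["B"] * 13)
        X = rng.normal(size=(26, 2))
        cv = RepeatedStratifiedKFold(n_splits=10, n_repeats=20, random_state=1)
        for _, test_idx in cv.split(X, y):
            counts = pd.Series(y[test_idx]).value_counts()
            assert abs(counts.get("A", 0) - counts.get("B", 0)) <= 1

    def test_same_seed_reproducible(self, rng):
        X, y = two_clusters(rng, n=13, sep=1.0)
        r1 = stratified_repeated_cv(X, y, ClassifierSpec(), seed=3)
        r2 = stratified_repeated_cv(X, y, ClassifierSpec(), seed=3)
        assert np.array_equal(r1.fold_accuracies, r2.fold_accuracies)

    def test_small_class_degrades_with_warning(self, rng):
        X = rng.normal(size=(12, 2))
        y = np.array(["A"] * 6 + ["B"] * 6)
        with pytest.warns(UserWarning, match="fold"):
            rep = stratified_repeated_cv(X, y, ClassifierSpec(k=3), k=10, repeats=2)
        assert len(rep.fold_accuracies) == 2 * 6

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ConfigurationError):
            stratified_repeated_cv(X, np.array(["A"] * 10), ClassifierSpec())

    def test_test_fold_outlier_cannot_leak_into_standardization(self, rng):
        # predictions for other test rows are unchanged when one test row
        # becomes extreme: standardization parameters come from training only
        X, y = two_clusters(rng, n=20, sep=3.0)
        spec = ClassifierSpec()
        from propsig.classify import _predict

        test = rng.normal(1.5, 1, (6, 3))
        base = _predict(spec, X, y, test)
        test_out = test.copy()
        test_out[0] = 1e6
        pert = _predict(spec, X, y, test_out)
        assert np.array_equal(base[1:], pert[1:])


class TestProblems:
    @pytest.fixture()
    def table(self, rng):
        rows = []
        for cls, dip, mu in [("NT", "AVI/AVI", 0.0), ("MT", "PAV/AVI", 3.0), ("ST", "PAV/PAV", 6.0)]:
            for j in range(13):
                feats = rng.normal(mu, 1.0, 7)
                rows.append(
                    {"subject_id": f"{cls}{j}", "taster_label": cls, "diplotype": dip,
                     **{f"f{i}": v for i, v in enumerate(feats, 1)}}
                )
        return pd.DataFrame(rows)

    def test_nt_vs_st_drops_mt(self, table):
        labels = map_labels(table, "nt_vs_st")
        assert labels.notna().sum() == 26
        assert set(labels.dropna()) == {"NT", "ST"}

    def test_nt_vs_tasters_merges(self, table):
        labels = map_labels(table, "nt_vs_tasters")
        assert (labels == "Taster").sum() == 26

    def test_diplotype_labels(self, table):
        labels = map_labels(table, "diplotype")
        assert set(labels) == {"AVI/AVI", "PAV/AVI", "PAV/PAV"}

    def test_run_problem_end_to_end(self, table):
        rep = run_problem(table, "nt_vs_st", ClassifierSpec(), combo="best1", seed=1)
        assert len(rep.fold_accuracies) == 200
        assert rep.mean > 0.9
        assert rep.confusion.to_numpy().sum() == 200 * 26 / 10

    def test_empty_class_rejected(self, table):
        only_nt = table[table.taster_label == "NT"]
        with pytest.raises(ConfigurationError):
            run_problem(only_nt, "nt_vs_st", ClassifierSpec())
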