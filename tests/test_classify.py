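import math

import numpy as np
import pandas as pd
import pytest

from oracles import dempster_combine, metrics_formulas

from aspasep import classify as cl


class TestMetrics:
    def test_perfect_classifier(self):
        assert cl.metrics(cl.ConfusionCounts(50, 50, 0, 0)) == (1.0, 1.0, 1.0, 1.0)

    def test_perfectly_wrong(self):
        acc, mcc, sn, sp = cl.metrics(cl.ConfusionCounts(0, 0, 50, 50))
        assert acc == 0.0 and mcc == -1.0

    def test_printed_formula_example(self):
        acc, mcc, sn, sp = cl.metrics(cl.ConfusionCounts(tp=40, tn=35, fp=15, fn=10))
        assert (acc, sn, sp) == (0.75, 0.8, 0.7)
        assert mcc == pytest.approx(0.5025, abs=1e-4)

    def test_zero_marginal_gives_zero_mcc(self):
        acc, mcc, _, _ = cl.metrics(cl.ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert mcc == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cl.metrics(cl.ConfusionCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cl.ConfusionCounts(-1, 0, 0, 0)

    def test_swap_invariance_of_acc_and_mcc(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 30, size=4))
            if tp + tn + fp + fn == 0:
                continue
            a1, m1, _, _ = cl.metrics(cl.ConfusionCounts(tp, tn, fp, fn))
            a2, m2, _, _ = cl.metrics(cl.ConfusionCounts(tn, tp, fn, fp))
            assert a1 == a2
            assert m1 == pytest.approx(m2, abs=1e-12)

    def test_grid_against_formula_oracle(self):
        grid = range(0, 5)
        n_checked = 0
        for tp in grid:
            for tn in grid:
                for fp in grid:
                    for fn in grid:
                        if tp + tn + fp + fn == 0:
                            continue
                        got = cl.metrics(cl.ConfusionCounts(tp, tn, fp, fn))
                        want = metrics_formulas(tp, tn, fp, fn)
                        for g, w in zip(got, want):
                            if math.isnan(w):
                                assert math.isnan(g)
                            else:
                                assert g == pytest.approx(w, abs=1e-12)
                        n_checked += 1
        assert n_checked >= 200


def two_blob_matrix(rng, n=40, gap=6.0, dim=3):
    Xa = rng.normal(0.0, 1.0, size=(n, dim))
    Xb = rng.normal(gap, 1.0, size=(n, dim))
    frame = pd.DataFrame(np.vstack([Xa, Xb]), columns=[f"f{i}" for i in range(dim)])
    frame.insert(0, "label", ["a"] * n + ["b"] * n)
    frame.insert(0, "id", [f"s{i}" for i in range(2 * n)])
    return frame


class TestOETKNN:
    def test_k1_predicts_nearest_neighbor_label(self):
        X = np.array([[0.0], [10.0]])
        y = np.array(["a", "b"])
        model = cl.OETKNNClassifier(k=1).fit(X, y)
        assert list(model.predict([[1.0], [9.0]])) == ["a", "b"]

    def test_unanimous_neighbors_win(self):
        X = np.array([[0.0], [0.5], [1.0], [50.0]])
        y = np.array(["a", "a", "a", "b"])
        model = cl.OETKNNClassifier(k=3).fit(X, y)
        assert model.predict([[0.4]])[0] == "a"

    def test_three_neighbor_masses_match_hand_combination(self):
        # equilateral geometry: fix gamma so masses are hand-computable
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        y = np.array(["a", "b", "a"])
        alpha = 0.9
        model = cl.OETKNNClassifier(k=3, alpha=alpha, gamma={"a": 1.0, "b": 1.0}).fit(X, y)
        test = np.array([[0.25, 0.25]])
        d2 = ((X - test) ** 2).sum(axis=1)
        masses = []
        for cls, dd in zip(y, d2):
            m = alpha * math.exp(-dd)
            masses.append(
                {"A": m if cls == "a" else 0.0, "B": m if cls == "b" else 0.0, "AB": 1 - m}
            )
        expected = dempster_combine(masses)
        bel = model._beliefs(test)[0]
        assert bel[0] == pytest.approx(expected["A"], rel=1e-10)
        assert bel[1] == pytest.approx(expected["B"], rel=1e-10)
        assert bel[2] == pytest.approx(expected["AB"], rel=1e-10)

    def test_alpha_to_zero_falls_back_to_neighbor_majority(self):
        # four equidistant neighbors: 3 of class b, 1 of class a
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0], [9.0, 9.0]])
        y = np.array(["b", "b", "b", "a", "a"])
        model = cl.OETKNNClassifier(k=4, alpha=1e-8, gamma={"a": 1.0, "b": 1.0}).fit(X, y)
        assert model.predict([[0.0, 0.0]])[0] == "b"
        # 2-2 tie among equidistant neighbors -> lower class index ("a")
        y_tie = np.array(["b", "b", "a", "a", "a"])
        model = cl.OETKNNClassifier(k=4, alpha=1e-8, gamma={"a": 1.0, "b": 1.0}).fit(X, y_tie)
        assert model.predict([[0.0, 0.0]])[0] == "a"

    def test_k_exceeding_training_rejected(self):
        X = np.zeros((3, 2))
        y = np.array(["a", "a", "b"])
        with pytest.raises(ValueError):
            cl.OETKNNClassifier(k=5).fit(X, y)

    def test_deterministic_tie_break_by_row_index(self):
        # two training points exactly equidistant from the query
        X = np.array([[1.0], [-1.0], [5.0]])
        y = np.array(["a", "b", "b"])
        model = cl.OETKNNClassifier(k=1, gamma={"a": 1.0, "b": 1.0}).fit(X, y)
        assert model.predict([[0.0]])[0] == "a"  # row 0 wins the tie


class TestCovarianceDiscriminant:
    def test_spherical_classes_reduce_to_nearest_mean(self, rng):
        Xa = rng.normal(0, 1, size=(100, 2))
        Xb = rng.normal(8, 1, size=(100, 2))
        model = cl.CovarianceDiscriminant().fit(
            np.vstack([Xa, Xb]), np.array(["a"] * 100 + ["b"] * 100)
        )
        assert model.predict([[0.5, 0.5]])[0] == "a"
        assert model.predict([[7.5, 8.5]])[0] == "b"

    def test_class_mean_point_classified_to_that_class(self, rng):
        Xa = rng.normal(0, 1, size=(50, 3))
        Xb = rng.normal(10, 1, size=(50, 3))
        model = cl.CovarianceDiscriminant().fit(
            np.vstack([Xa, Xb]), np.array(["a"] * 50 + ["b"] * 50)
        )
        assert model.predict([Xa.mean(axis=0)])[0] == "a"

    def test_two_dimensional_hand_computed_scores(self):
        # diagonal covariances, ridge 0: scores computable by hand
        Xa = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        Xb = Xa + np.array([10.0, 0.0])
        X = np.vstack([Xa, Xb])
        y = np.array(["a"] * 4 + ["b"] * 4)
        model = cl.CovarianceDiscriminant(ridge=0.0).fit(X, y)
        test = np.array([[1.0, 1.0]])
        # per class: mean (1,1)/(11,1); cov = diag(4/3, 4/3) (ddof=1)
        var = 4.0 / 3.0
        maha_a = 0.0
        maha_b = ((1 - 11) ** 2 + 0.0) / var
        logdet = 2 * math.log(var)
        logprior = math.log(0.5)
        expected_a = -maha_a - logdet + 2 * logprior
        expected_b = -maha_b - logdet + 2 * logprior
        scores = model.scores(test)[0]
        assert scores[0] == pytest.approx(expected_a, rel=1e-9)
        assert scores[1] == pytest.approx(expected_b, rel=1e-9)

    def test_small_class_rejected(self):
        X = np.zeros((3, 2))
        y = np.array(["a", "b", "b"])
        with pytest.raises(ValueError):
            cl.CovarianceDiscriminant().fit(X, y)


class TestSklearnBacked:
    def test_svm_separable_training_accuracy(self, rng):
        frame = two_blob_matrix(rng, n=20)
        X = frame[["f0", "f1", "f2"]].to_numpy()
        y = frame["label"].to_numpy()
        from sklearn.svm import SVC

        model = SVC(kernel="linear").fit(X, y)
        assert (model.predict(X) == y).all()

    def test_random_forest_single_split_feature(self, rng):
        from sklearn.ensemble import RandomForestClassifier

        X = np.r_[np.zeros((20, 1)), np.ones((20, 1))]
        y = np.array(["a"] * 20 + ["b"] * 20)
        model = RandomForestClassifier(n_estimators=1, max_depth=1, random_state=0).fit(X, y)
        assert (model.predict(X) == y).all()


class TestCrossValidate:
    def test_separable_data_all_classifiers_perfect(self, rng):
        frame = two_blob_matrix(rng, n=25, gap=10.0)
        for name in cl.CLASSIFIER_NAMES:
            rep = cl.cross_validate(frame, cl.ClassifierSpec(name), folds=5, seed=17)
            assert rep.acc == 1.0
            assert rep.mcc == 1.0

    def test_permuted_labels_near_chance(self, rng):
        frame = two_blob_matrix(rng, n=50, gap=8.0)
        frame["label"] = rng.permutation(frame["label"].to_numpy())
        rep = cl.cross_validate(frame, cl.ClassifierSpec("oet_knn"), folds=5, seed=17)
        assert abs(rep.acc - 0.5) < 0.15
        assert abs(rep.mcc) < 0.3

    def test_same_seed_identical_report(self, rng):
        frame = two_blob_matrix(rng, n=20, gap=3.0)
        r1 = cl.cross_validate(frame, cl.ClassifierSpec("random_forest"), seed=7)
        r2 = cl.cross_validate(frame, cl.ClassifierSpec("random_forest"), seed=7)
        assert r1 == r2

    def test_metrics_recomputable_from_pooled_counts(self, rng):
        frame = two_blob_matrix(rng, n=25, gap=2.0)
        rep = cl.cross_validate(frame, cl.ClassifierSpec("svm"), folds=5, seed=17)
        acc, mcc, sn, sp = cl.metrics(rep.pooled_counts)
        assert (rep.acc, rep.mcc, rep.sn, rep.sp) == (acc, mcc, sn, sp)
        total = sum(c.total for c in rep.fold_counts)
        assert total == len(frame)

    def test_too_many_folds_rejected(self, rng):
        frame = two_blob_matrix(rng, n=3)
        with pytest.raises(ValueError):
            cl.cross_validate(frame, cl.ClassifierSpec("svm"), folds=5)

    def test_jackknife_runs(self, rng):
        frame = two_blob_matrix(rng, n=10, gap=8.0)
        rep = cl.cross_validate(frame, cl.ClassifierSpec("covariance_discriminant"),
                                jackknife=True)
        assert rep.cv_scheme == "jackknife"
        assert rep.acc == 1.0
        assert math.isnan(rep.auc_mean)

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError):
            cl.ClassifierSpec("neural_net")


def test_report_frame_and_writers(tmp_path, rng):
    import json

    frame = two_blob_matrix(rng, n=15, gap=6.0)
    reports = cl.evaluate_classifiers(frame, folds=3, seed=17)
    assert [r.classifier_name for r in reports] == list(cl.CLASSIFIER_NAMES)
    table = cl.report_frame(reports)
    assert set(table.columns) == {"classifier", "acc", "mcc", "auc_mean", "auc_sd", "sn", "sp"}
    cl.write_reports(reports, tmp_path / "r.tsv", tmp_path / "r.json")
    payload = json.loads((tmp_path / "r.json").read_text())
    assert len(payload) == 4
    assert all("pooled_counts" in entry for entry in payload)
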