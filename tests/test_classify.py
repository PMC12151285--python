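import numpy as np
import pandas as pd
import pytest

from gainet.classify import (
    ClassifyError,
    ModelSpec,
    augment_minority,
    concatenate_features,
    cross_validate,
    evaluate,
    fit_predict,
    stratified_split,
)
from gainet.io_formats import LabelTable, OmicsKind, OmicsMatrix


def _labels(class_sizes: dict[str, int]) -> LabelTable:
    rows = []
    i = 0
    for c, n in class_sizes.items():
        for _ in range(n):
            rows.append({"sample_id": f"s{i:03d}", "class_label": c})
            i += 1
    return LabelTable(pd.DataFrame(rows))


def _blobs(class_sizes: dict[str, int], sep=6.0, n_features=5, seed=0):
    """Well-separated Gaussian classes."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k, (c, n) in enumerate(class_sizes.items()):
        centre = np.zeros(n_features)
        centre[k % n_features] = sep
        X.append(rng.normal(centre, 1.0, size=(n, n_features)))
        y += [c] * n
    return np.vstack(X), np.array(y)


class TestStratifiedSplit:
    def test_exact_divisibility_gives_equal_test_classes(self):
        lt = _labels({"A": 25, "B": 25, "C": 25, "D": 25})
        split = stratified_split(lt, 0.2, seed=3)
        assert len(split.test_sample_ids) == 20
        te = lt.labels_for(split.test_sample_ids)
        assert all((te == c).sum() == 5 for c in "ABCD")

    def test_same_seed_same_split(self):
        lt = _labels({"A": 30, "B": 12})
        s1 = stratified_split(lt, 0.2, seed=7)
        s2 = stratified_split(lt, 0.2, seed=7)
        assert s1.test_sample_ids == s2.test_sample_ids

    def test_disjoint_and_exhaustive(self):
        lt = _labels({"A": 13, "B": 9, "C": 5})
        s = stratified_split(lt, 0.25, seed=1)
        assert not set(s.train_sample_ids) & set(s.test_sample_ids)
        assert sorted(s.train_sample_ids + s.test_sample_ids) == sorted(lt.table["sample_id"])

    def test_singleton_class_raises_naming_it(self):
        lt = _labels({"A": 9, "B": 1})
        with pytest.raises(ClassifyError, match="B"):
            stratified_split(lt, 0.2)


class TestAugmentMinority:
    def test_balanced_input_unchanged(self):
        X, y = _blobs({"A": 10, "B": 10})
        Xa, ya = augment_minority(X, y, seed=0)
        assert np.array_equal(Xa, X) and np.array_equal(ya, y)

    def test_minority_counts_reach_balance_band(self):
        X, y = _blobs({"A": 40, "B": 10, "C": 10, "D": 10}, seed=2)
        Xa, ya = augment_minority(X, y, seed=5)
        counts = {c: (ya == c).sum() for c in "ABCD"}
        assert counts["A"] == 40
        assert all(36 <= counts[c] <= 44 for c in "BCD")

    def test_originals_preserved_first(self):
        X, y = _blobs({"A": 30, "B": 8}, seed=3)
        Xa, ya = augment_minority(X, y, seed=1)
        assert np.array_equal(Xa[: len(X)], X)
        assert np.array_equal(ya[: len(y)], y)

    def test_synthetic_points_are_same_class_convex_combinations(self):
        X, y = _blobs({"A": 40, "B": 12}, n_features=4, seed=4)
        Xa, ya = augment_minority(X, y, seed=9)
        synth = Xa[len(X):]
        assert np.all(ya[len(y):] == "B")
        originals = X[y == "B"]
        for p in synth:
            on_some_segment = False
            for i in range(len(originals)):
                for z in range(len(originals)):
                    if i == z:
                        continue
                    d = originals[z] - originals[i]
                    v = p - originals[i]
                    denom = d @ d
                    if denom == 0:
                        continue
                    u = (v @ d) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.linalg.norm(v - u * d) < 1e-8:
                        on_some_segment = True
                        break
                if on_some_segment:
                    break
            assert on_some_segment

    def test_deterministic_given_seed(self):
        X, y = _blobs({"A": 25, "B": 7}, seed=6)
        a = augment_minority(X, y, seed=11)
        b = augment_minority(X, y, seed=11)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_tiny_class_falls_back_to_duplication(self):
        X = np.vstack([np.zeros((10, 3)), np.ones((1, 3))])
        y = np.array(["A"] * 10 + ["B"])
        with pytest.warns(UserWarning, match="duplicat"):
            Xa, ya = augment_minority(X, y, seed=0)
        assert (ya == "B").sum() == 10
        assert np.array_equal(Xa[len(X):], np.ones((9, 3)))


class TestConcatenate:
    def _m(self, kind, n_feat, samples):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1 if kind is OmicsKind.METHYLATION_BETA else 50,
                           size=(n_feat, len(samples)))
        return OmicsMatrix([f"{kind.value[:2]}{i}" for i in range(n_feat)], samples, vals, kind)

    def test_widths_add_and_names_prefixed(self):
        s = ["a", "b", "c"]
        out = concatenate_features(
            [
                self._m(OmicsKind.MRNA_COUNTS, 5, s),
                self._m(OmicsKind.MIRNA_COUNTS, 2, s),
                self._m(OmicsKind.METHYLATION_BETA, 4, s),
            ]
        )
        assert out.shape == (3, 11)
        assert list(out.index) == s
        assert out.columns[0].startswith("mrna_counts:")
        assert out.columns[-1].startswith("methylation_beta:")

    def test_single_matrix_identity_values(self):
        s = ["a", "b"]
        m = self._m(OmicsKind.MRNA_COUNTS, 3, s)
        out = concatenate_features([m])
        np.testing.assert_array_equal(out.to_numpy(), m.values.T)

    def test_misaligned_samples_raise(self):
        m1 = self._m(OmicsKind.MRNA_COUNTS, 2, ["a", "b"])
        m2 = self._m(OmicsKind.MIRNA_COUNTS, 2, ["b", "a"])
        with pytest.raises(ClassifyError):
            concatenate_features([m1, m2])


class TestFitPredictAndEvaluate:
    def test_separable_logistic_is_perfect(self):
        X, y = _blobs({"A": 20, "B": 20}, sep=10, seed=1)
        pred, scores, classes = fit_predict(ModelSpec("logistic_ovr"), X, y, X)
        assert (pred == y).all()
        np.testing.assert_allclose(scores.sum(axis=1), 1.0)

    def test_knn_k1_memorizes_training_set(self):
        X, y = _blobs({"A": 15, "B": 15}, sep=2, seed=2)
        pred, _, _ = fit_predict(ModelSpec("knn", {"knn_neighbors": 1}), X, y, X)
        assert (pred == y).all()

    def test_random_forest_deterministic_given_seed(self):
        X, y = _blobs({"A": 20, "B": 20, "C": 20}, sep=3, seed=3)
        runs = [fit_predict(ModelSpec("random_forest", {"seed": 5}), X, y, X)[0] for _ in range(2)]
        assert np.array_equal(runs[0], runs[1])

    def test_unknown_model_and_hyperparameter_rejected(self):
        with pytest.raises(ClassifyError):
            ModelSpec("svm")
        with pytest.raises(ClassifyError):
            ModelSpec("knn", {"learning_rate": 0.1})

    def test_test_rows_left_bit_identical(self):
        X, y = _blobs({"A": 12, "B": 12}, seed=4)
        Xte = X[:8].copy()
        before = Xte.copy()
        fit_predict(ModelSpec("logistic_ovr"), X, y, Xte)
        assert np.array_equal(Xte, before)

    def test_every_model_family_learns_easy_data(self):
        X, y = _blobs({"A": 30, "B": 30, "C": 30, "D": 30}, sep=8, seed=5)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(y))
        tr, te = idx[:90], idx[90:]
        for model, hp in [
            ("logistic_ovr", {}),
            ("knn", {"knn_neighbors": 4}),
            ("random_forest", {"seed": 0}),
            ("feedforward_net", {"hidden_sizes": (32, 16, 8), "epochs": 300, "seed": 0}),
        ]:
            pred, scores, classes = fit_predict(ModelSpec(model, hp), X[tr], y[tr], X[te])
            rep = evaluate(y[te], pred, scores, classes)
            assert rep.accuracy >= 0.9, model
            # the evaluation must reproduce accuracy from its own confusion matrix
            assert rep.accuracy == pytest.approx(
                np.diag(rep.confusion).sum() / rep.confusion.to_numpy().sum()
            )

    def test_perfect_predictions_score_one(self):
        y = np.array(["A", "B", "A", "B"])
        scores = np.array([[0.9, 0.1], [0.1, 0.9], [0.8, 0.2], [0.2, 0.8]])
        rep = evaluate(y, y, scores, np.array(["A", "B"]))
        assert rep.accuracy == 1.0 and rep.macro_f1 == 1.0 and rep.auroc_macro == 1.0

    def test_never_predicted_class_gets_zero_precision_and_f1(self):
        y_true = np.array(["A", "A", "B", "B"])
        y_pred = np.array(["A", "A", "A", "A"])
        rep = evaluate(y_true, y_pred)
        assert rep.precision["B"] == 0.0 and rep.f1["B"] == 0.0

    def test_hand_computed_confusion_metrics(self):
        # confusion [[3,1],[2,4]]: A: p=3/5, r=3/4; B: p=4/5, r=4/6
        y_true = np.array(["A"] * 4 + ["B"] * 6)
        y_pred = np.array(["A", "A", "A", "B", "A", "A", "B", "B", "B", "B"])
        rep = evaluate(y_true, y_pred)
        assert rep.precision["A"] == pytest.approx(3 / 5)
        assert rep.recall["A"] == pytest.approx(3 / 4)
        assert rep.f1["A"] == pytest.approx(2 * (3 / 5) * (3 / 4) / (3 / 5 + 3 / 4))
        assert rep.precision["B"] == pytest.approx(4 / 5)
        assert rep.recall["B"] == pytest.approx(4 / 6)
        assert np.array_equal(rep.confusion.to_numpy(), [[3, 1], [2, 4]])

    def test_random_scores_auroc_near_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.array(["A"] * 50 + ["B"] * 50)
            scores = rng.random((100, 2))
            scores /= scores.sum(axis=1, keepdims=True)
            aucs.append(evaluate(y, y, scores, np.array(["A", "B"])).auroc_macro)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


class TestCrossValidate:
    def test_fold_sizes_and_disjoint_validation(self):
        X, y = _blobs({"A": 15, "B": 10}, seed=7)
        reports = cross_validate(ModelSpec("logistic_ovr"), X, y, n_folds=5, seed=0)
        sizes = [r.confusion.to_numpy().sum() for r in reports]
        assert sum(sizes) == 25 and all(s == 5 for s in sizes)

    def test_deterministic_under_seed(self):
        X, y = _blobs({"A": 12, "B": 12}, seed=8)
        r1 = cross_validate(ModelSpec("random_forest", {"seed": 1}), X, y, 3, seed=4)
        r2 = cross_validate(ModelSpec("random_forest", {"seed": 1}), X, y, 3, seed=4)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.confusion.to_numpy(), b.confusion.to_numpy())
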