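"""Cross-validation harness and micro-averaged multiclass metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mugsel import (
    ConfusionMatrix,
    ExpressionMatrix,
    LRSettings,
    SelectorSpec,
    confusion,
    cross_validate,
    fit_predict_lr,
    mcc_multiclass,
    micro_metrics,
    micro_roc_auc,
    stratified_folds,
)


class TestStratifiedFolds:
    def test_perfect_balance(self):
        labels = {f"s{i}": ("a" if i < 5 else "b") for i in range(10)}
        folds = stratified_folds(labels, k=5, seed=0)
        for f in range(5):
            test = folds.test_samples(f)
            assert len(test) == 2
            assert {labels[s] for s in test} == {"a", "b"}

    def test_determinism_and_seed_sensitivity(self):
        labels = {f"s{i}": ("a" if i % 2 else "b") for i in range(20)}
        a = stratified_folds(labels, k=5, seed=3).fold_of_sample
        b = stratified_folds(labels, k=5, seed=3).fold_of_sample
        assert a == b
        assert a != stratified_folds(labels, k=5, seed=4).fold_of_sample

    def test_unbalanced_class_counts_differ_by_at_most_one(self):
        labels = {f"a{i}": "a" for i in range(7)} | {f"b{i}": "b" for i in range(5)}
        folds = stratified_folds(labels, k=5, seed=1)
        for cls in ("a", "b"):
            per_fold = [
                sum(1 for s in folds.test_samples(f) if labels[s] == cls)
                for f in range(5)
            ]
            assert max(per_fold) - min(per_fold) <= 1

    def test_small_class_errors_with_name(self):
        labels = {"x1": "rare", "x2": "rare"} | {f"s{i}": "big" for i in range(9)}
        with pytest.raises(ValueError, match="rare"):
            stratified_folds(labels, k=5, seed=0)


class TestLogisticRegression:
    def test_separable_training_data_reproduced(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((5, 2))])
        y = np.array(["a"] * 5 + ["b"] * 5)
        pred, proba, classes = fit_predict_lr(X, y, X)
        assert list(pred) == list(y)
        assert proba.shape == (10, 2)

    def test_probabilities_monotone_in_indicator_feature(self):
        X = np.linspace(0, 1, 12).reshape(-1, 1)
        y = np.array(["lo"] * 6 + ["hi"] * 6)
        _, proba, classes = fit_predict_lr(X, y, X)
        hi_col = list(classes).index("hi")
        assert np.all(np.diff(proba[:, hi_col]) > 0)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.choice(["a", "b", "c"], size=30)
        out1 = fit_predict_lr(X, y, X, LRSettings(seed=5))
        out2 = fit_predict_lr(X, y, X, LRSettings(seed=5))
        assert np.array_equal(out1[1], out2[1])

    def test_non_finite_values_rejected(self):
        X = np.array([[1.0], [np.inf]])
        with pytest.raises(ValueError, match="non-finite"):
            fit_predict_lr(X, np.array(["a", "b"]), X)


class TestConfusion:
    def test_diagonal_and_single_column(self):
        y = ["a", "b", "c"]
        assert np.array_equal(confusion(y, y, y).counts, np.eye(3, dtype=int))
        all_a = confusion(["a", "b", "c"], ["a", "a", "a"], y).counts
        assert all_a[:, 0].sum() == 3 and all_a[:, 1:].sum() == 0

    def test_hand_tally_nine_samples(self):
        y_true = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        y_pred = ["a", "b", "a", "b", "b", "c", "c", "c", "a"]
        cm = confusion(y_true, y_pred, ["a", "b", "c"])
        assert np.array_equal(cm.counts, [[2, 1, 0], [0, 2, 1], [1, 0, 2]])

    def test_length_mismatch_and_label_cover(self):
        with pytest.raises(ValueError, match="length mismatch"):
            confusion(["a"], ["a", "b"], ["a", "b"])
        with pytest.raises(ValueError, match="cover"):
            confusion(["a"], ["z"], ["a", "b"])


class TestMicroMetrics:
    def test_perfect_predictions(self):
        cm = ConfusionMatrix(["a", "b"], np.diag([5, 5]))
        m = micro_metrics(cm)
        assert m == {"accuracy": 1.0, "micro_f": 1.0, "micro_fpr": 0.0}

    def test_two_class_hand_aggregation(self):
        # one-vs-rest aggregation of [[45,5],[10,40]]:
        # accuracy 85/100; micro-FPR (5+10)/(5+40+10+45) = 0.15
        cm = ConfusionMatrix(["a", "b"], np.array([[45, 5], [10, 40]]))
        m = micro_metrics(cm)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["micro_fpr"] == pytest.approx(0.15)
        assert m["micro_f"] == pytest.approx(0.85)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(0, 50), min_size=4, max_size=4),
            min_size=4,
            max_size=4,
        )
    )
    def test_micro_f_equals_accuracy_single_label(self, rows):
        """Algebraic identity: in single-label multiclass data the aggregate
        FP and FN counts coincide, so micro-F1 == accuracy."""
        counts = np.array(rows)
        if counts.sum() == 0:
            counts[0, 0] = 1
        cm = ConfusionMatrix([f"c{i}" for i in range(4)], counts)
        m = micro_metrics(cm)
        assert m["micro_f"] == pytest.approx(m["accuracy"], abs=1e-12)

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError, match="empty"):
            micro_metrics(ConfusionMatrix(["a"], np.zeros((1, 1), dtype=int)))


class TestMcc:
    def test_perfect_and_independent(self):
        assert mcc_multiclass(ConfusionMatrix(list("abc"), np.diag([3, 3, 3]))) == 1.0
        uniform = ConfusionMatrix(list("abc"), np.full((3, 3), 4))
        assert mcc_multiclass(uniform) == pytest.approx(0.0)

    def test_binary_closed_form_value(self):
        cm = ConfusionMatrix(["a", "b"], np.array([[45, 5], [10, 40]]))
        expected = (45 * 40 - 5 * 10) / math.sqrt(50 * 55 * 45 * 50)
        assert mcc_multiclass(cm) == pytest.approx(expected)

    def test_reduces_to_binary_closed_form(self, rng):
        for _ in range(300):
            c = rng.integers(0, 30, size=(2, 2))
            tp, fn, fp, tn = c[0, 0], c[0, 1], c[1, 0], c[1, 1]
            den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            expected = ((tp * tn - fp * fn) / math.sqrt(den)) if den else 0.0
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                got = mcc_multiclass(ConfusionMatrix(["a", "b"], c))
            if c.sum():
                assert got == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn_on_multiclass(self, rng):
        from sklearn.metrics import matthews_corrcoef

        y_true = rng.choice(["a", "b", "c"], size=200)
        y_pred = np.where(rng.random(200) < 0.6, y_true, rng.choice(list("abc"), 200))
        cm = confusion(y_true, y_pred, ["a", "b", "c"])
        assert mcc_multiclass(cm) == pytest.approx(
            matthews_corrcoef(y_true, y_pred), abs=1e-12
        )

    def test_degenerate_denominator_warns_zero(self):
        cm = ConfusionMatrix(["a", "b"], np.array([[7, 0], [0, 0]]))
        with pytest.warns(UserWarning, match="degenerate"):
            assert mcc_multiclass(cm) == 0.0


def oracle_pairwise_auc(y_bin, scores):
    """O(n^2) pairwise-comparison AUC with ties counted half."""
    pos = [s for s, t in zip(scores, y_bin) if t]
    neg = [s for s, t in zip(scores, y_bin) if not t]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestMicroRocAuc:
    def test_one_hot_scores_are_perfect(self):
        y = ["a", "b", "c", "a"]
        scores = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        assert micro_roc_auc(y, scores, ["a", "b", "c"]) == 1.0

    def test_constant_scores_are_chance(self):
        y = ["a", "b", "a"]
        assert micro_roc_auc(y, np.full((3, 2), 0.5), ["a", "b"]) == pytest.approx(0.5)

    def test_matches_pairwise_oracle_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        from sklearn.preprocessing import label_binarize

        labels = ["a", "b", "c"]
        for _ in range(20):
            n = int(rng.integers(6, 15))
            y = rng.choice(labels, size=n)
            while len(set(y)) < 2:
                y = rng.choice(labels, size=n)
            scores = rng.random((n, 3))
            got = micro_roc_auc(y, scores, labels)
            onehot = label_binarize(y, classes=labels).ravel().astype(bool)
            assert got == pytest.approx(
                oracle_pairwise_auc(onehot, scores.ravel()), abs=1e-12
            )
            assert got == pytest.approx(
                roc_auc_score(onehot, scores.ravel()), abs=1e-12
            )

    def test_single_class_flat_labels_error(self):
        with pytest.raises(ValueError, match="single class"):
            micro_roc_auc(["a", "a"], np.ones((2, 1)), ["a"])


# --- cross-validation harness -------------------------------------------------


def _separable_matrix(n_per_class=10, n_genes=12, seed=0):
    rng = np.random.default_rng(seed)
    classes = ["a", "b", "c"]
    samples, labels, rows = [], {}, []
    for ci, cls in enumerate(classes):
        for i in range(n_per_class):
            sid = f"{cls}{i}"
            samples.append(sid)
            labels[sid] = cls
            base = np.abs(rng.normal(1, 0.1, n_genes))
            base[ci * 3 : ci * 3 + 3] += 10  # disjoint high-expression blocks
            rows.append(base)
    return ExpressionMatrix(samples, [f"g{j}" for j in range(n_genes)],
                            np.array(rows)), labels


class TestCrossValidate:
    def test_separable_cohort_perfect_accuracy(self):
        X, labels = _separable_matrix()
        report = cross_validate(X, labels, SelectorSpec(method="all"), k=5, seed=0)
        assert report.mean("accuracy") == 1.0
        assert report.mean("micro_f") == 1.0
        assert report.mean("micro_fpr") == 0.0
        assert report.mean("mcc") == 1.0

    def test_same_seed_same_report(self):
        X, labels = _separable_matrix(seed=3)
        r1 = cross_validate(X, labels, SelectorSpec(method="mi_topk", k=4), seed=9)
        r2 = cross_validate(X, labels, SelectorSpec(method="mi_topk", k=4), seed=9)
        assert r1.per_fold == r2.per_fold
        assert r1.to_json() == r2.to_json()

    def test_micro_f_equals_accuracy_in_reports(self):
        X, labels = _separable_matrix(seed=5)
        report = cross_validate(X, labels, SelectorSpec(method="relieff", k=6,
                                                        params={"n_neighbors": 3}))
        assert report.per_fold["micro_f"] == pytest.approx(
            report.per_fold["accuracy"]
        )

    def test_data_driven_selection_never_sees_test_samples(self):
        """A selector that records the sample IDs it was fit on must never be
        shown a held-out sample."""
        X, labels = _separable_matrix()
        folds_seen = []

        def spy_selector(X_train, y_train):
            folds_seen.append(set(X_train.sample_ids))
            return X_train.gene_ids[:4]

        spec = SelectorSpec(method="custom", params={"fn": spy_selector})
        folds = cross_validate(X, labels, spec, k=5, seed=11)
        assignment = stratified_folds(labels, k=5, seed=11)
        assert len(folds_seen) == 5
        for f, seen in enumerate(folds_seen):
            held_out = set(assignment.test_samples(f))
            assert not (seen & held_out)

    def test_whole_dataset_selection_flag(self):
        X, labels = _separable_matrix()
        seen = []
        spec = SelectorSpec(
            method="custom",
            params={"fn": lambda Xt, yt: (seen.append(len(Xt.sample_ids)) or
                                          Xt.gene_ids[:4])},
        )
        cross_validate(X, labels, spec, k=5, seed=0, leak_free=False)
        assert seen == [len(X.sample_ids)]  # fit once, on everything

    def test_fixed_gene_set_applied_to_all_folds(self):
        X, labels = _separable_matrix()
        spec = SelectorSpec(method="fixed", genes={"g0", "g3", "g6", "g9"},
                            params={"name": "fixed4"})
        report = cross_validate(X, labels, spec, k=5, seed=0)
        assert report.config["n_features_per_fold"] == [4] * 5

    def test_unlabeled_sample_errors(self):
        X, labels = _separable_matrix()
        labels = dict(labels)
        del labels[X.sample_ids[0]]
        with pytest.raises(ValueError, match="unlabeled"):
            cross_validate(X, labels)

    def test_table_row_format(self):
        X, labels = _separable_matrix()
        row = cross_validate(X, labels, SelectorSpec(method="all"), seed=0).table_row()
        cells = row.split("\t")
        assert cells[0] == "all" and cells[1] == "12"
        assert cells[2] == "100.00 ±0.00"  # accuracy as a two-decimal percent
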