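"""SVM grading and the per-class metric suite."""

import numpy as np
import pytest
from sklearn.model_selection import cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from oagrade.classify_eval import (SVMConfig, evaluate, f1_from_pr,
                                   report_to_text, svm_predict, svm_train)
from oagrade.core_io import Grade
from oagrade.synthetic_data import SyntheticSpec, generate_features

from conftest import make_table


def _concentric(seed, n=60):
    """Four classes on concentric rings: radially, not linearly, separable."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for g in range(4):
        r = 1.0 + 2.0 * g + rng.normal(0, 0.25, n)
        th = rng.uniform(0, 2 * np.pi, n)
        xs.append(np.c_[r * np.cos(th), r * np.sin(th)])
        ys += [g] * n
    return make_table(np.vstack(xs), labels=ys)


class TestSVM:
    def test_separable_training_accuracy(self):
        table = generate_features(SyntheticSpec(
            n_per_class=10, n_informative=4, n_noise=6, separation=10.0, seed=0))
        model = svm_train(table, SVMConfig(kernel="linear"))
        pred, scores = svm_predict(model, table)
        assert np.array_equal(pred, table.labels)
        assert scores.shape == (40, 4)
        assert np.array_equal(scores.argmax(axis=1), pred)

    def test_deterministic_predictions(self, small_table):
        probe = generate_features(SyntheticSpec(
            n_per_class=5, n_informative=4, n_noise=6, separation=6.0, seed=99))
        p1, s1 = svm_predict(svm_train(small_table, SVMConfig(seed=1)), probe)
        p2, s2 = svm_predict(svm_train(small_table, SVMConfig(seed=1)), probe)
        assert np.array_equal(p1, p2) and np.array_equal(s1, s2)

    def test_row_equivariance(self, small_table):
        model = svm_train(small_table)
        perm = np.random.default_rng(0).permutation(small_table.n_samples)
        p1, s1 = svm_predict(model, small_table)
        p2, s2 = svm_predict(model, small_table.select_rows(perm))
        assert np.array_equal(p1[perm], p2)
        np.testing.assert_allclose(s1[perm], s2)

    def test_single_class_rejected(self):
        table = make_table(np.random.default_rng(0).normal(size=(10, 3)),
                           labels=[2] * 10)
        with pytest.raises(ValueError, match="two classes"):
            svm_train(table)

    def test_dimension_mismatch_rejected(self, small_table):
        model = svm_train(small_table)
        with pytest.raises(ValueError, match="features"):
            svm_predict(model, small_table.select_features(range(5)))

    def test_cubic_beats_linear_on_concentric_classes(self):
        """Radial class structure needs the polynomial kernel."""
        for seed in range(3):
            table = _concentric(seed)
            cubic = cross_val_score(
                make_pipeline(StandardScaler(),
                              SVC(kernel="poly", degree=3, coef0=1.0)),
                table.values, table.labels, cv=5).mean()
            linear = cross_val_score(
                make_pipeline(StandardScaler(), SVC(kernel="linear")),
                table.values, table.labels, cv=5).mean()
            assert cubic > linear

    def test_ovo_scheme_scores_shape(self, small_table):
        model = svm_train(small_table, SVMConfig(multiclass_scheme="one-vs-one"))
        pred, scores = svm_predict(model, small_table)
        assert scores.shape == (small_table.n_samples, 4)
        assert np.array_equal(scores.argmax(axis=1), pred)


class TestF1:
    @pytest.mark.parametrize("precision,recall,expected", [
        (1.000, 0.889, 0.941),   # moderate class, PCA path, HE stain
        (0.833, 1.000, 0.909),   # severe class, PCA path, HE stain
        (1.000, 0.800, 0.889),   # severe class, PCA path, SafO stain
        (1.000, 0.941, 0.970),   # moderate class, ALO path, SafO stain
        (1.0, 1.0, 1.0),
    ])
    def test_published_worked_examples(self, precision, recall, expected):
        assert round(f1_from_pr(precision, recall), 3) == expected

    def test_degenerate_and_invalid(self):
        assert f1_from_pr(0.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            f1_from_pr(1.2, 0.5)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.repeat(np.arange(4), 5)
        scores = np.eye(4)[y] * 10.0
        report = evaluate(y, y, scores)
        assert report.overall_accuracy == 1.0
        for g in Grade:
            m = report.per_class[g]
            assert (m.sensitivity, m.precision, m.specificity, m.f1) == (1, 1, 1, 1)
            assert report.auc[g] == 1.0

    def test_against_brute_force_recount(self):
        """Per-class TP/TN/FP/FN match an explicit sample-by-sample count."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            y_true = rng.integers(0, 4, size=80)
            y_pred = rng.integers(0, 4, size=80)
            report = evaluate(y_true, y_pred)
            for g in Grade:
                tp = np.sum((y_true == g.value) & (y_pred == g.value))
                fn = np.sum((y_true == g.value) & (y_pred != g.value))
                fp = np.sum((y_true != g.value) & (y_pred == g.value))
                tn = np.sum((y_true != g.value) & (y_pred != g.value))
                assert report.confusion.one_vs_rest(g) == (tp, tn, fp, fn)
                m = report.per_class[g]
                if tp + fn:
                    assert m.sensitivity == pytest.approx(tp / (tp + fn))
                if tp + fp:
                    assert m.precision == pytest.approx(tp / (tp + fp))
                assert m.specificity == pytest.approx(tn / (tn + fp))
                assert m.accuracy == pytest.approx((tp + tn) / 80)
            assert report.overall_accuracy == pytest.approx(
                np.mean(y_true == y_pred))

    def test_confusion_marginals(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 4, size=60)
        y_pred = rng.integers(0, 4, size=60)
        report = evaluate(y_true, y_pred)
        counts = report.confusion.counts
        assert counts.sum() == 60
        tps = [report.confusion.one_vs_rest(g)[0] for g in Grade]
        assert sum(tps) == np.trace(counts)
        for g in Grade:
            assert counts[g.value].sum() == np.sum(y_true == g.value)
            assert counts[:, g.value].sum() == np.sum(y_pred == g.value)

    def test_auc_reversal_antisymmetry(self):
        rng = np.random.default_rng(2)
        y = np.repeat(np.arange(4), 20)
        scores = rng.standard_normal((80, 4))
        fwd = evaluate(y, scores.argmax(axis=1), scores)
        rev = evaluate(y, scores.argmax(axis=1), -scores)
        for g in Grade:
            assert fwd.auc[g] + rev.auc[g] == pytest.approx(1.0)

    def test_absent_class_flagged_not_crashed(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 1, 1, 1])
        report = evaluate(y_true, y_pred)
        severe = report.per_class[Grade.SEVERE]
        assert severe.sensitivity == 0.0 and "sensitivity" in severe.undefined
        assert "undefined" in report_to_text(report)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([0, 1], [0])
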