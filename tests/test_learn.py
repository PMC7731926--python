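"""G-mean metrics, leakage-safe stratified CV, grid ranking, model fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import labels_for
from tfsum.learn import (
    GridResult,
    PropertySentenceClassifier,
    TrainedPropertyModel,
    cv_summary,
    fit_property_model,
    fold_metrics,
    grid_search,
    predict_labels,
    stratified_cv,
)


class TestFoldMetrics:
    def test_perfect_predictions(self):
        r = fold_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert r.gmean == 1.0 and r.sensitivity == 1.0 and r.specificity == 1.0

    def test_all_negative_predictions_zero_gmean(self):
        r = fold_metrics([0, 0, 0, 0], [1, 0, 0, 0])
        assert r.sensitivity == 0.0 and r.gmean == 0.0

    def test_closed_form_point_nine(self):
        # sens 0.81 (81/100 positives found), spec 1.0 -> gmean sqrt(0.81) = 0.9
        truth = [1] * 100 + [0] * 50
        preds = [1] * 81 + [0] * 19 + [0] * 50
        r = fold_metrics(preds, truth)
        assert r.sensitivity == pytest.approx(0.81)
        assert r.specificity == 1.0
        assert r.gmean == pytest.approx(0.9)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            fold_metrics([1, 0], [1, 1])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)
    )
    def test_gmean_symmetry_and_accuracy_identity(self, tp, fn, tn, fp):
        """G-mean is symmetric in sens/spec and equals accuracy when sens = spec."""
        if tp + fn == 0 or tn + fp == 0:
            return
        truth = [1] * (tp + fn) + [0] * (tn + fp)
        preds = [1] * tp + [0] * fn + [0] * tn + [1] * fp
        r = fold_metrics(preds, truth)
        # symmetry: swap class roles
        truth_sw = [1 - t for t in truth]
        preds_sw = [1 - p for p in preds]
        r_sw = fold_metrics(preds_sw, truth_sw)
        assert r.gmean == pytest.approx(r_sw.gmean)
        if r.sensitivity == r.specificity:
            accuracy = (tp + tn) / len(truth)
            assert r.gmean == pytest.approx(accuracy)


@pytest.fixture(scope="module")
def cv_setup(recovery_corpus, annotated_summaries):
    y = labels_for(recovery_corpus, "ACT")
    return annotated_summaries, y


class TestStratifiedCv:
    @pytest.mark.parametrize("sampler", ["NONE", "RANDOM_US"])
    def test_validation_folds_preserve_imbalance(self, cv_setup, sampler):
        """Under-sampling never touches the validation fold (leakage guard)."""
        X, y = cv_setup
        est = PropertySentenceClassifier(sampler=sampler, random_state=0)
        folds = stratified_cv(X, y, est, k=10, seed=0)
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        seen_val = []
        for fold in folds:
            val_y = y[fold.val_indices]
            assert val_y.sum() in (n_pos // 10, n_pos // 10 + 1)
            assert (1 - val_y).sum() in (n_neg // 10, n_neg // 10 + 1)
            assert set(fold.val_indices).isdisjoint(fold.sampled_train_indices)
            assert set(fold.sampled_train_indices) <= set(fold.train_indices)
            seen_val.extend(fold.val_indices)
        assert sorted(seen_val) == list(range(len(y)))

    def test_too_few_positives_rejected(self, cv_setup):
        X, _ = cv_setup
        y = np.zeros(len(X), dtype=int)
        y[:3] = 1
        with pytest.raises(ValueError, match="positive"):
            stratified_cv(X, y, PropertySentenceClassifier(), k=10, seed=0)


class TestGridSearch:
    def make_result(self, median, iqr, skew, i):
        return GridResult(PropertySentenceClassifier(), [], median, iqr, skew, i)

    def test_ranking_keys(self):
        from tfsum.learn import rank_grid_results

        results = [
            self.make_result(0.7, 0.01, 0.0, 0),
            self.make_result(0.9, 0.10, 0.5, 1),
            self.make_result(0.9, 0.02, 0.9, 2),
            self.make_result(0.9, 0.02, -0.1, 3),
        ]
        # median first, then IQR, then |skewness|
        assert [r.grid_index for r in rank_grid_results(results)] == [3, 2, 1, 0]

    def test_single_config_grid(self, cv_setup):
        X, y = cv_setup
        est = PropertySentenceClassifier(combo="NER_FOR_LEMMA", random_state=0)
        ranked = grid_search(X, y, [est], k=10, seed=0)
        assert len(ranked) == 1 and 0 <= ranked[0].median_gmean <= 1

    def test_empty_grid_rejected(self, cv_setup):
        X, y = cv_setup
        with pytest.raises(ValueError):
            grid_search(X, y, [], k=10, seed=0)


class TestFitAndPredict:
    def test_separable_training_gmean_one(self, cv_setup):
        X, y = cv_setup
        est = PropertySentenceClassifier(combo="NER_FOR_LEMMA", random_state=0)
        est.fit(X, y)
        r = fold_metrics(est.predict(X), y)
        assert r.gmean >= 0.99

    def test_deterministic_decision_values(self, cv_setup):
        X, y = cv_setup
        a = PropertySentenceClassifier(random_state=3).fit(X, y).decision_function(X[:20])
        b = PropertySentenceClassifier(random_state=3).fit(X, y).decision_function(X[:20])
        assert np.array_equal(a, b)

    def test_poly_without_degree_rejected(self, cv_setup):
        X, y = cv_setup
        with pytest.raises(ValueError, match="degree"):
            PropertySentenceClassifier(kernel="poly").fit(X, y)

    def test_one_class_dataset_rejected(self, cv_setup):
        X, _ = cv_setup
        with pytest.raises(ValueError):
            PropertySentenceClassifier().fit(X[:10], np.zeros(10, dtype=int))

    def test_unfitted_predict_rejected(self, cv_setup):
        X, _ = cv_setup
        with pytest.raises(ValueError, match="not fitted"):
            PropertySentenceClassifier().predict(X[:2])

    def test_empty_sentence_list_predicts_empty(self, cv_setup):
        X, y = cv_setup
        est = PropertySentenceClassifier(random_state=0).fit(X, y)
        assert len(est.predict([])) == 0

    def test_multi_label_assignment(self, recovery_corpus, annotated_summaries):
        """Applying several property models yields a label set per sentence."""
        models = {}
        for prop in ("ACT", "RP"):
            y = labels_for(recovery_corpus, prop)
            models[prop] = PropertySentenceClassifier(
                combo="NER_FOR_LEMMA", random_state=0
            ).fit(annotated_summaries, y)
        labels = predict_labels(models, annotated_summaries[:50])
        assert len(labels) == 50
        assert all(ls <= {"ACT", "RP"} for ls in labels)

    def test_model_round_trip(self, tmp_path, cv_setup):
        X, y = cv_setup
        model = fit_property_model(
            X, y, PropertySentenceClassifier(random_state=1), "ACT", seed=1, run_cv=False
        )
        model.save(tmp_path / "ACT")
        loaded = TrainedPropertyModel.load(tmp_path / "ACT")
        assert np.array_equal(
            loaded.classifier.decision_function(X[:25]),
            model.classifier.decision_function(X[:25]),
        )
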