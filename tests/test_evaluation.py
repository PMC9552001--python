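import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn import metrics as skm

from reprotox.evaluation import (
    CVResult,
    ConfusionCounts,
    compute_metrics,
    confusion_from_predictions,
    external_validate,
    loael_stratified_sensitivity,
    make_folds,
    run_repeated_cv,
)

from conftest import base_specs, make_dataset


class TestFoldPlan:
    def test_275_chemicals_give_five_folds_of_55(self):
        plan = make_folds(275, folds=5, seed=0)
        assert plan.sizes() == [55] * 5

    def test_remainder_spread_over_leading_folds(self):
        plan = make_folds(7, folds=5, seed=1)
        assert sorted(plan.sizes(), reverse=True) == [2, 2, 1, 1, 1]

    def test_same_seed_same_plan(self):
        a = make_folds(40, seed=9)
        b = make_folds(40, seed=9)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_every_chemical_assigned_exactly_once(self):
        plan = make_folds(53, folds=5, seed=2)
        assert len(plan.assignment) == 53
        assert set(plan.assignment) == set(range(5))

    def test_stratified_preserves_class_balance(self):
        y = np.array([1] * 30 + [0] * 70)
        plan = make_folds(100, folds=5, seed=3, stratified=True, y=y)
        for f in range(5):
            pos = y[plan.assignment == f].sum()
            assert 5 <= pos <= 7  # 30/5 = 6 +/- 1

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(10, folds=1)

    def test_more_folds_than_chemicals_rejected(self):
        with pytest.raises(ValueError):
            make_folds(3, folds=5)


class TestMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert m.accuracy == m.balanced_accuracy == m.mcc == 1.0

    def test_chance_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert m.accuracy == 0.5 and m.mcc == 0.0 and m.balanced_accuracy == 0.5

    def test_degenerate_denominators(self):
        # no positives at all: sensitivity and PPR undefined, MCC zero
        m = compute_metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert np.isnan(m.sensitivity) and np.isnan(m.positive_predictive_rate)
        assert m.mcc == 0.0 and m.specificity == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=1)

    @settings(max_examples=200, deadline=None)
    @given(tp=st.integers(0, 100), tn=st.integers(0, 100),
           fp=st.integers(0, 100), fn=st.integers(0, 100))
    def test_against_label_list_oracle(self, tp, tn, fp, fn):
        """Metrics from counts equal sklearn metrics on the raw label lists."""
        if tp + tn + fp + fn == 0:
            return
        y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
        y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
        m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        assert m.accuracy == pytest.approx(skm.accuracy_score(y_true, y_pred))
        if tp + fn:
            assert m.sensitivity == pytest.approx(
                skm.recall_score(y_true, y_pred, pos_label=1, zero_division=np.nan))
        if tn + fp:
            assert m.specificity == pytest.approx(
                skm.recall_score(y_true, y_pred, pos_label=0, zero_division=np.nan))
        if not (np.isnan(m.sensitivity) or np.isnan(m.specificity)):
            assert m.balanced_accuracy == pytest.approx((m.sensitivity + m.specificity) / 2)
        if tp + fp:
            assert m.positive_predictive_rate * (tp + fp) == pytest.approx(tp)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert m.mcc == pytest.approx(skm.matthews_corrcoef(y_true, y_pred), abs=1e-12)

    def test_confusion_from_predictions_counts(self):
        c = confusion_from_predictions([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 1, 1)


class TestRepeatedCV:
    def test_each_chemical_predicted_once_per_iteration_per_model(self, small_cv,
                                                                  strong_filtered):
        preds = small_cv.predictions
        counts = preds.groupby(["iteration", "model"])["id"].agg(["count", "nunique"])
        assert (counts["count"] == strong_filtered.n_chemicals).all()
        assert (counts["nunique"] == strong_filtered.n_chemicals).all()

    def test_consensus_votes_match_base_labels(self, small_cv):
        preds = small_cv.predictions
        it0 = preds[preds["iteration"] == 0]
        base = it0[it0["model"] != "consensus"].pivot(index="id", columns="model",
                                                      values="predicted")
        cons = it0[it0["model"] == "consensus"].set_index("id")
        np.testing.assert_array_equal(
            base.sum(axis=1).loc[cons.index].to_numpy(),
            cons["n_positive_votes"].to_numpy())

    def test_aggregate_recomputable_from_per_iteration_log(self, small_cv):
        agg = small_cv.aggregate()
        per = small_cv.per_iteration
        for model in ("DT", "consensus"):
            sub = per[per["model"] == model]["mcc"]
            assert agg.loc[model, ("mean", "mcc")] == pytest.approx(sub.mean(), abs=1e-12)
            assert agg.loc[model, ("sd", "mcc")] == pytest.approx(sub.std(ddof=1), abs=1e-12)

    def test_rerun_with_same_seed_is_identical(self, strong_filtered):
        a = run_repeated_cv(strong_filtered, base_specs(3), iterations=1, seed=3)
        b = run_repeated_cv(strong_filtered, base_specs(3), iterations=1, seed=3)
        pd.testing.assert_frame_equal(a.per_iteration, b.per_iteration)
        pd.testing.assert_frame_equal(a.predictions, b.predictions)

    def test_missing_spec_rejected(self, strong_filtered):
        specs = base_specs()
        del specs["SVM"]
        with pytest.raises(ValueError, match="SVM"):
            run_repeated_cv(strong_filtered, specs, iterations=1)

    def test_zero_iterations_rejected(self, strong_filtered):
        with pytest.raises(ValueError):
            run_repeated_cv(strong_filtered, base_specs(), iterations=0)


class TestLoaelStratification:
    def _fake_cv(self, ids, true, predicted):
        frames = []
        for model in ("DT", "DF", "RF", "kNN", "SVM", "LDA", "LR", "consensus"):
            frames.append(pd.DataFrame({
                "iteration": 0, "model": model, "id": ids, "true": true,
                "probability": np.asarray(predicted, float), "predicted": predicted,
            }))
        preds = pd.concat(frames, ignore_index=True)
        return CVResult(pd.DataFrame(), preds, iterations=1, folds=5, seed=0)

    def test_perfect_strong_missed_weak(self):
        ids = ["a", "b", "c", "d"]
        loael = [10.0, 50.0, 500.0, 5000.0]  # two strong, two weak
        ds = make_dataset(np.zeros((4, 2)), [1, 1, 1, 1], loael)
        cv = self._fake_cv(ids=list(ds.ids), true=[1, 1, 1, 1], predicted=[1, 1, 0, 0])
        out = loael_stratified_sensitivity(cv, ds, cutoff=100.0)
        assert (out["strong_sensitivity"] == 1.0).all()
        assert (out["weak_sensitivity"] == 0.0).all()

    def test_empty_stratum_is_undefined_not_zero(self):
        ds = make_dataset(np.zeros((2, 2)), [1, 1], [500.0, 900.0])
        cv = self._fake_cv(ids=list(ds.ids), true=[1, 1], predicted=[1, 0])
        out = loael_stratified_sensitivity(cv, ds, cutoff=1.0)  # below all LOAELs
        assert out["strong_sensitivity"].isna().all()
        assert out["weak_sensitivity"].notna().all()

    def test_positive_without_loael_rejected(self):
        ds = make_dataset(np.zeros((2, 2)), [1, 0], [np.nan, np.nan])
        cv = self._fake_cv(ids=list(ds.ids), true=[1, 0], predicted=[1, 0])
        with pytest.raises(ValueError, match="without LOAEL"):
            loael_stratified_sensitivity(cv, ds)


class TestExternalValidation:
    def test_overlapping_id_rejected_by_name(self, strong_filtered):
        with pytest.raises(ValueError, match=strong_filtered.ids[0]):
            external_validate(strong_filtered, strong_filtered.take([0, 1, 2, 3]),
                              base_specs())

    def test_metrics_cover_all_eight_models(self, strong_study, strong_filtered):
        ext = strong_study.external.select_descriptors(
            strong_filtered.table.descriptor_names)
        result = external_validate(strong_filtered, ext, base_specs(1))
        assert set(result.metrics["model"]) == {"DT", "DF", "RF", "kNN", "SVM",
                                                "LDA", "LR", "consensus"}
        assert len(result.predictions) == 8 * ext.n_chemicals
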