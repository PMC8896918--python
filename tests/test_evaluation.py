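"""Cases, cross-validation, classifier adapters, confusion metrics."""

import math

import numpy as np
import pytest

from epiwave.evaluation import (
    CVSpec,
    ClassifierSpec,
    ConfusionMatrix,
    MetricsReport,
    best_per_case_classifier,
    build_cases,
    compute_metrics,
    confusion_from_predictions,
    fit_predict,
    grid_evaluate,
    kfold_split,
    make_case,
    run_case,
)
from epiwave.features import build_feature_table
from epiwave.synthetic import SynthSpec, generate_dataset

ALL_KINDS = ("SVM", "KNN", "NB", "DT")


class TestCases:
    def test_canonical_case_list(self):
        cases = build_cases()
        assert len(cases) == 17
        assert sum(1 for c in cases if c.n_classes == 2) == 16
        assert [c.name for c in cases[:4]] == ["A-E", "B-E", "C-E", "D-E"]
        assert cases[-2].name == "AB-CD" and cases[-1].name == "AB-CD-E"

    def test_a_e_groups_and_positive_class(self):
        case = make_case("A-E")
        assert case.class_groups == (frozenset("A"), frozenset("E"))
        assert case.positive_class == 1
        assert case.class_of("E") == 1

    def test_abcd_e_grouping(self):
        case = make_case("ABCD-E")
        assert case.class_groups[0] == frozenset("ABCD")
        assert case.class_groups[1] == frozenset("E")

    def test_three_class_case(self):
        case = make_case("AB-CD-E")
        assert case.n_classes == 3 and case.positive_class == 2

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_case("AB-BE")

    def test_unknown_label_lookup(self):
        with pytest.raises(KeyError):
            make_case("A-E").class_of("Z")


class TestKFold:
    def test_stratified_balanced_fold_sizes(self):
        y = [0] * 100 + [1] * 100
        folds = kfold_split(y, CVSpec(n_folds=10, seed=1))
        for _, test_idx in folds:
            assert test_idx.size == 20
            assert np.sum(np.asarray(y)[test_idx]) == 10  # 10 per class

    def test_partition_property(self):
        y = [0] * 37 + [1] * 23
        folds = kfold_split(y, CVSpec(n_folds=5, seed=3))
        seen = np.concatenate([t for _, t in folds])
        assert sorted(seen) == list(range(60))
        for train_idx, test_idx in folds:
            assert not set(train_idx) & set(test_idx)
            assert len(set(train_idx) | set(test_idx)) == 60

    def test_leave_one_out_boundary(self):
        y = [0, 1, 0, 1]
        folds = kfold_split(y, CVSpec(n_folds=4, stratified=False, seed=0))
        assert all(t.size == 1 for _, t in folds)

    def test_small_class_under_stratification_rejected(self):
        y = [0] * 50 + [1] * 5
        with pytest.raises(ValueError, match="fewer than 10"):
            kfold_split(y, CVSpec(n_folds=10))

    def test_fold_assignment_depends_only_on_seed(self):
        y = [0] * 30 + [1] * 30
        a = kfold_split(y, CVSpec(n_folds=5, seed=9))
        b = kfold_split(y, CVSpec(n_folds=5, seed=9))
        for (_, ta), (_, tb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)


class TestFitPredict:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_wide_margin_perfectly_separated(self, kind, rng):
        train_X = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(10, 0.1, 20)])[:, None]
        train_y = np.array([0] * 20 + [1] * 20)
        test_X = np.array([[0.05], [9.9], [0.2], [10.3]])
        preds = fit_predict(ClassifierSpec(kind), train_X, train_y, test_X)
        np.testing.assert_array_equal(preds, [0, 1, 0, 1])

    def test_knn_unanimous_neighbourhood(self):
        train_X = np.array([[0.0], [0.1], [0.2], [5.0], [5.1]])
        train_y = np.array([0, 0, 0, 1, 1])
        preds = fit_predict(ClassifierSpec("KNN"), train_X, train_y, [[0.05]])
        assert preds[0] == 0

    def test_knn_tie_broken_by_nearest_neighbour(self):
        # three classes, one neighbour each: the closest one wins
        train_X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        train_y = np.array([2, 1, 0, 0, 1, 2])
        preds = fit_predict(
            ClassifierSpec("KNN"), train_X, train_y, [[0.4], [10.4]],
        )
        assert preds[0] == 2  # nearest neighbour (0.0) is class 2
        assert preds[1] == 0  # nearest neighbour (10.0) is class 0

    def test_knn_equidistant_tie_lowest_class_index(self):
        # k=3, one vote per class; classes 1 and 2 equidistant and nearest,
        # so the tie falls through to the lowest class index
        train_X = np.array([[-1.0], [1.0], [2.0]])
        train_y = np.array([2, 1, 0])
        preds = fit_predict(ClassifierSpec("KNN"), train_X, train_y, [[0.0]])
        assert preds[0] == 1

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_deterministic_given_seed(self, kind, rng):
        train_X = rng.standard_normal((60, 3))
        train_y = rng.integers(0, 2, 60)
        if len(np.unique(train_y)) < 2:
            train_y[0] = 1 - train_y[0]
        test_X = rng.standard_normal((20, 3))
        spec = ClassifierSpec(kind, seed=4)
        a = fit_predict(spec, train_X, train_y, test_X)
        b = fit_predict(spec, train_X, train_y, test_X)
        np.testing.assert_array_equal(a, b)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            fit_predict(
                ClassifierSpec("SVM"), [[0.0], [1.0], [2.0]], [0, 1, 1],
                [[0.5]], n_classes=3,
            )

    def test_non_finite_feature_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            fit_predict(
                ClassifierSpec("NB"), [[0.0], [np.nan]], [0, 1], [[0.5]]
            )

    def test_column_mismatch_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            fit_predict(
                ClassifierSpec("DT"), [[0.0, 1.0], [1.0, 0.0]], [0, 1], [[0.5]]
            )

    def test_invalid_specs(self):
        with pytest.raises(ValueError, match="odd"):
            ClassifierSpec("KNN", {"k": 4})
        with pytest.raises(ValueError, match="valid kinds"):
            ClassifierSpec("MLP")


class TestConfusion:
    def test_perfect_agreement(self):
        cm = confusion_from_predictions([0, 1, 1, 0], [0, 1, 1, 0])
        assert cm.FP == cm.FN == 0
        assert cm.CCP == cm.TPT == 4

    def test_direct_counting(self):
        y_true = [1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        cm = confusion_from_predictions(y_true, y_pred, positive_class=1)
        assert (cm.TP, cm.FN, cm.TN, cm.FP) == (5, 1, 6, 0)

    def test_all_wrong(self):
        cm = confusion_from_predictions([0, 0, 1, 1], [1, 1, 0, 0])
        assert cm.TP == cm.TN == 0 and cm.CCP == 0

    def test_three_class_one_vs_rest(self):
        cm = confusion_from_predictions(
            [0, 0, 1, 1, 2, 2], [0, 1, 1, 2, 2, 2], positive_class=2, n_classes=3
        )
        assert cm.table.shape == (3, 3)
        assert cm.CCP == 4 and cm.TPT == 6
        tp, fp, tn, fn = cm.one_vs_rest(2)
        assert (tp, fp, tn, fn) == (2, 1, 3, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_from_predictions([0, 1], [0])


class TestMetrics:
    def test_perfect_matrix(self):
        cm = ConfusionMatrix.from_counts(tp=6, fp=0, tn=6, fn=0)
        m = compute_metrics(cm)
        assert m.accuracy == m.sensitivity == m.specificity == 100.0
        assert m.ppv == m.npv == 100.0
        assert m.mcc == 1.0

    def test_nearly_perfect_matrix(self):
        m = compute_metrics(ConfusionMatrix.from_counts(tp=5, fp=0, tn=6, fn=1))
        assert m.sensitivity == pytest.approx(83.33, abs=0.005)
        assert m.specificity == 100.0
        assert m.ppv == 100.0
        assert m.npv == pytest.approx(100 * 6 / 7)
        assert m.accuracy == pytest.approx(100 * 11 / 12)
        assert m.mcc == pytest.approx(0.845, abs=0.0005)

    def test_all_wrong_symmetric_matrix(self):
        m = compute_metrics(ConfusionMatrix.from_counts(tp=0, fp=6, tn=0, fn=6))
        assert m.accuracy == 0.0
        assert m.mcc == -1.0

    def test_undefined_ratio_is_nan_and_zero_denominator_mcc(self):
        # no positive truths or predictions: sens and ppv undefined, MCC 0
        m = compute_metrics(ConfusionMatrix.from_counts(tp=0, fp=0, tn=8, fn=0))
        assert math.isnan(m.sensitivity) and math.isnan(m.ppv)
        assert m.specificity == 100.0 and m.mcc == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix.from_counts(0, 0, 0, 0))

    def test_fold_average_skips_undefined(self):
        a = MetricsReport(100, 100, 100, 100, 100, 1.0)
        b = MetricsReport(50, 50, 50, math.nan, 50, 0.0)
        m = MetricsReport.mean([a, b])
        assert m.accuracy == 75.0 and m.ppv == 100.0 and m.mcc == 0.5


class TestRunCase:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_separable_synthetic_d5_mav(self, fast_table, kind):
        res = run_case(
            make_case("H-S"), fast_table, ("D5", "MAV"),
            ClassifierSpec(kind, seed=0), CVSpec(n_folds=10, seed=0),
        )
        assert res.metrics.accuracy >= 95.0
        assert res.n_samples == 60

    def test_missing_set_label_rejected(self, fast_table):
        with pytest.raises(ValueError, match="absent"):
            run_case(make_case("A-E"), fast_table, ("D5", "MAV"))

    def test_repeat_run_identical(self, fast_table):
        kwargs = dict(
            feature_selector=("D5", "APEN"),
            classifier=ClassifierSpec("DT", seed=5),
            cv=CVSpec(n_folds=5, seed=5),
        )
        a = run_case(make_case("H-S"), fast_table, **kwargs)
        b = run_case(make_case("H-S"), fast_table, **kwargs)
        assert a == b

    def test_pooled_mode_metrics_in_bounds(self, fast_table):
        res = run_case(
            make_case("H-S"), fast_table, ("A5", "STD"),
            ClassifierSpec("NB"), CVSpec(n_folds=5, seed=1), pooled=True,
        )
        assert 0 <= res.metrics.accuracy <= 100
        assert -1 <= res.metrics.mcc <= 1

    def test_label_permutation_null_is_chance_level(self, fast_table):
        """Shuffled labels destroy the separable structure: ~50% accuracy."""
        shuffled = fast_table.frame.copy()
        rng = np.random.default_rng(13)
        shuffled["set_label"] = rng.permutation(shuffled["set_label"].to_numpy())
        table = type(fast_table)(frame=shuffled, subbands_used=fast_table.subbands_used)
        res = run_case(
            make_case("H-S"), table, ("D5", "MAV"),
            ClassifierSpec("KNN", seed=0), CVSpec(n_folds=10, seed=0),
        )
        assert 40.0 <= res.metrics.accuracy <= 60.0

    def test_monotone_separation_in_seizure_amplitude(self):
        """More discharge amplitude never hurts D5-MAV separability (with slack)."""
        accs = []
        for amp in (55.0, 110.0, 220.0, 440.0):
            spec = SynthSpec(n_segments_per_class=20, segment_length=512,
                             seizure_amp=amp, seed=21)
            table = build_feature_table(generate_dataset(spec), subbands=("D5",))
            res = run_case(
                make_case("H-S"), table, ("D5", "MAV"),
                ClassifierSpec("KNN", seed=0), CVSpec(n_folds=5, seed=0),
            )
            accs.append(res.metrics.accuracy)
        for lo, hi in zip(accs, accs[1:]):
            assert hi >= lo - 5.0  # one-fold sampling slack
        assert accs[-1] >= accs[0]

    def test_three_class_run(self):
        spec = SynthSpec(n_segments_per_class=15, segment_length=512, seed=4)
        table = build_feature_table(
            generate_dataset(spec, three_class=True), subbands=("D5", "A5")
        )
        res = run_case(
            make_case("H-I-S"), table, "all",
            ClassifierSpec("DT", seed=0), CVSpec(n_folds=5, seed=0),
        )
        assert res.subband == "all" and 0 <= res.metrics.accuracy <= 100


class TestGrid:
    def test_result_counting(self, fast_table):
        results = grid_evaluate(
            fast_table, [make_case("H-S")],
            [ClassifierSpec("KNN"), ClassifierSpec("NB")],
            CVSpec(n_folds=5, seed=0),
            subbands=("D5", "A5"), features=("MAV", "STD"),
        )
        assert len(results) == 1 * 2 * 2 * 2

    def test_best_report_one_entry_per_case_classifier(self, fast_table):
        results = grid_evaluate(
            fast_table, [make_case("H-S")],
            [ClassifierSpec("KNN"), ClassifierSpec("NB")],
            CVSpec(n_folds=5, seed=0),
            subbands=("D5",), features=("MAV", "MINC"),
        )
        best = best_per_case_classifier(results)
        assert set(best) == {("H-S", "KNN"), ("H-S", "NB")}
        for res in best.values():
            assert res.metrics.accuracy == max(
                r.metrics.accuracy for r in results if r.classifier == res.classifier
            )

    def test_empty_inputs_rejected(self, fast_table):
        with pytest.raises(ValueError):
            grid_evaluate(fast_table, [], [ClassifierSpec("NB")])
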