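"""Model selection, tuning and evaluation protocol."""

import numpy as np
import pytest

import gliotex as gt
from gliotex.modeling import ALGORITHM_NAMES, report_from_confusion

from .conftest import random_feature_table
from .oracles import naive_ovr_auc


class TestReportFromConfusion:
    # rows = true class (GBM, HGG, LGG); diagonal = printed correct counts
    PROTOCOL_CONFUSION = np.array([[112, 10, 8], [12, 109, 8], [4, 4, 121]])

    def test_protocol_counts_reproduce_headline_accuracy(self):
        rep = report_from_confusion(self.PROTOCOL_CONFUSION)
        assert rep.accuracy_percent == pytest.approx(88.14, abs=0.005)
        assert rep.error_percent == pytest.approx(11.86, abs=0.005)
        assert rep.support == {"GBM": 130, "HGG": 129, "LGG": 129}

    def test_protocol_counts_reproduce_lgg_recall(self):
        rep = report_from_confusion(self.PROTOCOL_CONFUSION)
        assert round(rep.recall["LGG"], 2) == 0.94  # 121/129

    def test_metrics_recomputable_from_confusion(self, rng):
        C = rng.integers(0, 50, (3, 3))
        C += np.eye(3, dtype=int) * 50
        rep = report_from_confusion(C)
        assert rep.accuracy * C.sum() == pytest.approx(np.trace(C))
        for k, cls in enumerate(gt.CLASSES):
            assert rep.recall[cls] == pytest.approx(C[k, k] / C[k].sum())
            assert rep.precision[cls] == pytest.approx(C[k, k] / C[:, k].sum())


class TestCrossvalidation:
    def test_exactly_seven_algorithms(self, rng):
        table = random_feature_table(rng, (30, 30, 30), class_shift=3.0)
        cv = gt.crossvalidate_algorithms(table, k=5)
        assert set(cv.mean_accuracy) == set(ALGORITHM_NAMES)
        assert len(ALGORITHM_NAMES) == 7

    def test_separable_table_scores_near_one(self, rng):
        table = random_feature_table(rng, (40, 40, 40), class_shift=8.0)
        cv = gt.crossvalidate_algorithms(table, k=5)
        assert all(m > 0.95 for m in cv.mean_accuracy.values())
        assert all(s < 0.1 for s in cv.sd_accuracy.values())

    def test_label_permutation_drops_to_chance(self, rng):
        table = random_feature_table(rng, (40, 40, 40), class_shift=3.0)
        permuted = table.with_(labels=rng.permutation(table.labels))
        cv = gt.crossvalidate_algorithms(permuted, k=5)
        for mean in cv.mean_accuracy.values():
            assert mean == pytest.approx(1 / 3, abs=0.12)

    def test_winner_invariant_and_deterministic(self, rng):
        table = random_feature_table(rng, (25, 25, 25), class_shift=1.0)
        a = gt.crossvalidate_algorithms(table, k=5, seed=3)
        b = gt.crossvalidate_algorithms(table, k=5, seed=3)
        assert a.mean_accuracy == b.mean_accuracy and a.winner == b.winner

    def test_folds_reduced_with_warning_for_tiny_classes(self, rng):
        table = random_feature_table(rng, (6, 6, 6), class_shift=2.0)
        with pytest.warns(UserWarning):
            cv = gt.crossvalidate_algorithms(table, k=10)
        assert cv.k == 6


class TestBaseModelAndTuning:
    def test_separable_training_predictions_perfect(self, rng):
        table = random_feature_table(rng, (30, 30, 30), class_shift=8.0)
        model, _ = gt.train_base_model(table)
        rep = gt.evaluate_model(model, table)
        assert rep.accuracy == 1.0

    def test_confusion_row_sums_equal_supports(self, rng):
        train = random_feature_table(rng, (30, 30, 30), class_shift=1.0)
        test = random_feature_table(rng, (12, 9, 7), class_shift=1.0)
        model, rep = gt.train_base_model(train, test)
        for k, cls in enumerate(gt.CLASSES):
            assert rep.confusion[k].sum() == rep.support[cls]

    def test_single_point_grid_returned(self, rng):
        table = random_feature_table(rng, (15, 15, 15), class_shift=2.0)
        spec = {"n_estimators": [37], "max_depth": [5], "min_samples_split": [2],
                "min_samples_leaf": [1], "max_features": ["sqrt"], "bootstrap": [True]}
        params, _ = gt.tune_hyperparameters(table, grid_spec=spec, method="grid", k=3)
        assert params.n_estimators == 37 and params.max_depth == 5

    def test_grid_containing_defaults_never_scores_below_them(self, rng):
        from sklearn.model_selection import StratifiedKFold, cross_val_score
        from sklearn.ensemble import RandomForestClassifier

        table = random_feature_table(rng, (20, 20, 20), class_shift=1.0)
        spec = {"n_estimators": [100, 30], "max_depth": [None], "min_samples_split": [2],
                "min_samples_leaf": [1], "max_features": ["sqrt"], "bootstrap": [True]}
        params, tuned_cv = gt.tune_hyperparameters(table, grid_spec=spec, method="grid",
                                                   k=3, seed=0)
        cv = StratifiedKFold(3, shuffle=True, random_state=0)
        base_cv = cross_val_score(
            RandomForestClassifier(random_state=0),
            table.features.to_numpy(), table.labels, cv=cv,
        ).mean()
        assert tuned_cv >= base_cv - 1e-12

    def test_shallow_separable_problem_selects_small_depth(self, rng):
        # one feature thresholds the classes -> depth-2 trees suffice
        table = random_feature_table(rng, (25, 25, 25), n_features=3, class_shift=10.0)
        spec = {"n_estimators": [50], "max_depth": [2, 50], "min_samples_split": [2],
                "min_samples_leaf": [1], "max_features": ["sqrt"], "bootstrap": [True]}
        depths = []
        for seed in range(5):
            params, _ = gt.tune_hyperparameters(table, grid_spec=spec, method="grid",
                                                k=3, seed=seed)
            depths.append(params.max_depth)
        assert depths.count(2) >= 4  # simpler-model tie-break concentrates at depth 2

    def test_empty_grid_rejected(self, rng):
        table = random_feature_table(rng, (10, 10, 10))
        with pytest.raises(ValueError):
            gt.tune_hyperparameters(table, grid_spec={"n_estimators": []}, method="grid")

    def test_paper_tuned_preset_values(self):
        assert gt.PAPER_TUNED.n_estimators == 108
        assert gt.PAPER_TUNED.max_depth == 50
        assert gt.PAPER_TUNED.bootstrap is False


class TestEvaluate:
    def test_perfect_predictions_give_unit_metrics(self, rng):
        table = random_feature_table(rng, (20, 20, 20), class_shift=9.0)
        model, _ = gt.train_base_model(table)
        rep = gt.evaluate_model(model, table)
        assert all(v == 1.0 for v in rep.precision.values())
        assert all(v == 1.0 for v in rep.f1.values())
        assert all(a == 1.0 for a in rep.ovr_auc.values())

    def test_ovr_auc_matches_pairwise_oracle(self):
        from sklearn.metrics import roc_auc_score

        y = np.array([0, 0, 1, 1, 2, 2])
        proba = np.array([
            [0.7, 0.2, 0.1],
            [0.4, 0.5, 0.1],
            [0.3, 0.6, 0.1],
            [0.2, 0.5, 0.3],
            [0.1, 0.3, 0.6],
            [0.2, 0.2, 0.6],
        ])
        aucs = roc_auc_score(y, proba, multi_class="ovr", average=None)
        for cls in range(3):
            assert aucs[cls] == pytest.approx(naive_ovr_auc(y, proba[:, cls], cls))

    def test_absent_class_flagged_undefined(self, rng):
        train = random_feature_table(rng, (15, 15, 15), class_shift=2.0)
        test = random_feature_table(rng, (6, 6, 6), class_shift=2.0)
        keep = test.labels != 2
        test = test.with_(features=test.features[keep], labels=test.labels[keep])
        model, _ = gt.train_base_model(train)
        rep = gt.evaluate_model(model, test)
        assert rep.undefined_classes == ["LGG"]
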