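"""Feature-matrix construction, classifier contracts across all four
algorithms, evaluation-metric consistency and the sensitivity analyses."""

import numpy as np
import pandas as pd
import pytest

import upfburden as ub
from upfburden.classifier import ALGORITHMS, DistressClassifier, metrics_from_confusion
from upfburden.errors import SchemaError, ValidationError
from upfburden.features import FeatureMatrix, build_feature_matrix, default_feature_dictionary
from upfburden.synthetic import TRAUMA_ITEMS


class TestBuildFeatureMatrix:
    def test_default_dictionary_yields_108_features(self, feature_matrix):
        assert feature_matrix.n_features == 108

    def test_one_hot_groups_sum_to_one(self, feature_matrix):
        fd = default_feature_dictionary()
        offset = 0
        for col, levels in fd["categorical"].items():
            block = feature_matrix.X[:, offset : offset + len(levels)]
            np.testing.assert_array_equal(block.sum(axis=1), 1.0)
            offset += len(levels)

    def test_trauma_selection_sets_exactly_those_columns(self, scored_cohort, feature_matrix):
        row = scored_cohort.iloc[10]
        expected = {t for t in TRAUMA_ITEMS if row[t] == 1}
        names = feature_matrix.feature_names
        got = {
            t for t in TRAUMA_ITEMS if feature_matrix.X[10, names.index(t)] == 1.0
        }
        assert got == expected

    def test_row_permutation_permutes_rows_only(self, scored_cohort, paper_cfg):
        fd = default_feature_dictionary(paper_cfg)
        sub = scored_cohort.head(50)
        perm = np.random.default_rng(3).permutation(50)
        fm1 = build_feature_matrix(sub, fd)
        fm2 = build_feature_matrix(sub.iloc[perm].reset_index(drop=True), fd)
        np.testing.assert_array_equal(fm1.X[perm], fm2.X)
        assert fm1.feature_names == fm2.feature_names

    def test_unseen_level_raises_naming_record_and_column(self, scored_cohort, paper_cfg):
        bad = scored_cohort.head(5).copy()
        bad.loc[bad.index[2], "sleep_quality"] = "Transcendent"
        with pytest.raises(SchemaError, match="sleep_quality"):
            build_feature_matrix(bad, default_feature_dictionary(paper_cfg))

    def test_missing_income_maps_to_not_available_level(self, scored_cohort, feature_matrix):
        names = feature_matrix.feature_names
        j = names.index("income_band=Not available")
        missing = scored_cohort["income_band"].isna().to_numpy()
        np.testing.assert_array_equal(feature_matrix.X[:, j] == 1.0, missing)


def _toy_fm(n=600, p=6, seed=0, separable=False):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, (n, p)).astype(float)
    if separable:
        y = X[:, 0] > 0.5
    else:
        logits = X[:, 0] * 2.0 - X[:, 1] + rng.normal(0, 1, n)
        y = logits > 0.5
    return FeatureMatrix(X=X, feature_names=[f"f{i}" for i in range(p)], y=y)


class TestDistressClassifier:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_all_algorithms_fit_and_predict(self, algorithm):
        fm = _toy_fm()
        clf = DistressClassifier(algorithm=algorithm, random_state=1, n_estimators=30)
        clf.fit(fm.X, fm.y)
        proba = clf.predict_proba(fm.X)
        assert proba.shape == (len(fm.X), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert set(np.unique(clf.predict(fm.X))) <= {0, 1}

    def test_sklearn_param_interface(self):
        clf = DistressClassifier()
        params = clf.get_params()
        assert params["algorithm"] == "gradient_boosted_trees"
        clf.set_params(max_depth=2)
        assert clf.get_params()["max_depth"] == 2

    def test_fit_is_deterministic_given_seed(self):
        fm = _toy_fm()
        p1 = DistressClassifier(random_state=7, n_estimators=40).fit(fm.X, fm.y).predict_proba(fm.X)
        p2 = DistressClassifier(random_state=7, n_estimators=40).fit(fm.X, fm.y).predict_proba(fm.X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_labels_rejected(self):
        fm = _toy_fm()
        with pytest.raises(ValidationError):
            DistressClassifier().fit(fm.X, np.zeros(len(fm.X), dtype=bool))

    def test_separable_data_reaches_training_auc_near_one(self):
        from sklearn.metrics import roc_auc_score

        fm = _toy_fm(separable=True)
        clf = DistressClassifier(n_estimators=30).fit(fm.X, fm.y)
        auc = roc_auc_score(fm.y.astype(int), clf.predict_proba(fm.X)[:, 1])
        assert auc >= 0.99

    def test_permuted_labels_give_chance_test_auc(self):
        fm = _toy_fm(n=2000, seed=2)
        rng = np.random.default_rng(11)
        fm_null = FeatureMatrix(X=fm.X, feature_names=fm.feature_names, y=rng.permutation(fm.y))
        metrics = ub.repeated_split_eval(fm_null, n_repeats=3, seed=1, n_estimators=40)
        assert abs(metrics.auc - 0.5) < 0.05


class TestEvaluation:
    def test_f1_harmonic_identity_from_confusion_counts(self, rng):
        y_true = rng.integers(0, 2, 500)
        y_pred = rng.integers(0, 2, 500)
        tp = int(((y_true == 1) & (y_pred == 1)).sum())
        fp = int(((y_true == 0) & (y_pred == 1)).sum())
        fn = int(((y_true == 1) & (y_pred == 0)).sum())
        tn = int(((y_true == 0) & (y_pred == 0)).sum())
        m = metrics_from_confusion(tp, fp, fn, tn)
        assert m["f1"] == pytest.approx(
            2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"]), abs=1e-9
        )
        assert m["accuracy"] == pytest.approx((tp + tn) / 500, abs=1e-12)
        from sklearn.metrics import f1_score

        assert m["f1"] == pytest.approx(f1_score(y_true, y_pred), abs=1e-9)

    def test_macro_differs_from_pooled_on_imbalanced_example(self):
        # hand example: 90 negatives all predicted negative; 10 positives, 2
        # predicted positive. Pooled (positive-class) recall = 0.2; macro
        # recall = (1.0 + 0.2) / 2 = 0.6
        y_true = np.array([0] * 90 + [1] * 10)
        y_pred = np.array([0] * 90 + [0] * 8 + [1] * 2)
        from sklearn.metrics import precision_recall_fscore_support, recall_score

        macro = precision_recall_fscore_support(y_true, y_pred, average="macro", zero_division=0)
        pooled_recall = recall_score(y_true, y_pred)
        assert macro[1] == pytest.approx(0.6, abs=1e-9)
        assert pooled_recall == pytest.approx(0.2, abs=1e-9)

    def test_cross_validation_stable_across_k(self, feature_matrix):
        aucs = [
            ub.cross_validate(feature_matrix, k=k, seed=0, n_estimators=60).auc
            for k in (3, 5, 10)
        ]
        assert max(aucs) - min(aucs) < 0.03

    def test_perfect_predictor_feature_gives_auc_one(self, rng):
        fm = _toy_fm(n=800, seed=4)
        X = np.hstack([fm.X, fm.y.astype(float)[:, None]])
        fm2 = FeatureMatrix(X=X, feature_names=fm.feature_names + ["oracle"], y=fm.y)
        for k in (3, 5):
            assert ub.cross_validate(fm2, k=k, seed=0, n_estimators=30).auc > 0.999

    def test_fold_assignment_deterministic(self, feature_matrix):
        m1 = ub.cross_validate(feature_matrix, k=3, seed=9, n_estimators=40)
        m2 = ub.cross_validate(feature_matrix, k=3, seed=9, n_estimators=40)
        pd.testing.assert_frame_equal(m1.per_fold, m2.per_fold)

    def test_repeated_split_test_size(self, feature_matrix):
        """65/35 split: every repeat evaluates on 35% of the records."""
        m = ub.repeated_split_eval(feature_matrix, n_repeats=2, seed=0, n_estimators=40)
        assert len(m.per_fold) == 2
        # metrics on the paper-like cohort are materially above chance
        assert m.auc > 0.65
        assert m.accuracy > feature_matrix.y.mean()  # beats majority-class floor

    def test_invalid_k_and_train_frac_rejected(self, feature_matrix):
        with pytest.raises(ValidationError):
            ub.cross_validate(feature_matrix, k=1)
        with pytest.raises(ValidationError):
            ub.repeated_split_eval(feature_matrix, train_frac=1.5)


class TestSensitivity:
    def test_duplicate_column_is_dropped_with_negligible_auc_change(self):
        fm = _toy_fm(n=1500, seed=6)
        X = np.hstack([fm.X, fm.X[:, [0]]])
        fm2 = FeatureMatrix(X=X, feature_names=fm.feature_names + ["f0_copy"], y=fm.y)
        res = ub.drop_correlated_sensitivity(fm2, seed=0, n_estimators=60)
        assert res.dropped_features == ["f0_copy"]
        assert abs(res.delta_auc) < 0.03

    def test_independent_features_drop_nothing(self):
        fm = _toy_fm(n=1500, seed=7)
        res = ub.drop_correlated_sensitivity(fm, seed=0, n_estimators=60)
        assert res.dropped_features == []
        assert res.delta_auc == pytest.approx(0.0, abs=1e-12)

    def test_exclude_exposure_null_generator_changes_nothing_much(self):
        """When the exposure has no effect, removing its columns leaves AUC
        essentially unchanged."""
        cfg = ub.null_config(n_respondents=4000, seed=23)
        df, _ = ub.generate_cohort(cfg)
        sc = ub.score_cohort(df, cfg.item_is_problem)
        fm = build_feature_matrix(sc, default_feature_dictionary(cfg))
        res = ub.exclude_exposure_sensitivity(fm, seed=0, n_estimators=60)
        assert abs(res.delta_auc) < 0.03

    def test_exclude_exposure_drops_auc_when_effect_is_strong(self, feature_matrix):
        res = ub.exclude_exposure_sensitivity(feature_matrix, seed=0, n_estimators=60)
        assert res.delta_auc > 0.0
        assert len(res.dropped_features) == 5

    def test_missing_exposure_columns_rejected(self):
        fm = _toy_fm()
        with pytest.raises(ValidationError):
            ub.exclude_exposure_sensitivity(fm, exposure_columns=["upf_freq=Never"])


class TestCalibration:
    def test_calibrated_synthetic_probabilities_on_diagonal(self, rng):
        """Labels drawn from the model's own probabilities: observed rates sit
        on the diagonal within binomial error."""
        n = 20000
        p = rng.uniform(0.05, 0.95, n)
        y = rng.random(n) < p

        class _Fake:
            def predict_proba(self, X):
                return np.column_stack([1 - p, p])

        curve = ub.calibration_curve(_Fake(), np.zeros((n, 1)), y, n_bins=10)
        full = curve[curve["n"] > 100]
        err = np.abs(full["mean_predicted"] - full["observed_rate"])
        bound = 3 * np.sqrt(full["mean_predicted"] * (1 - full["mean_predicted"]) / full["n"])
        assert (err < bound).all()

    def test_empty_bins_get_n0_rows(self, gbt_bundle, feature_matrix):
        curve = ub.calibration_curve(
            gbt_bundle.model, feature_matrix.X[:200], feature_matrix.y[:200], n_bins=50
        )
        assert len(curve) == 50
        assert (curve.loc[curve["n"] == 0, "mean_predicted"].isna()).all()

    def test_fitted_model_observed_rate_roughly_monotone(self, gbt_bundle, feature_matrix):
        curve = ub.calibration_curve(
            gbt_bundle.model, feature_matrix.X, feature_matrix.y, n_bins=8
        )
        rates = curve.loc[curve["n"] >= 50, "observed_rate"].to_numpy()
        # allow small local inversions, require global upward sweep
        assert rates[-1] > rates[0]
        assert (np.diff(rates) > -0.05).all()


def test_model_bundle_json_round_trip(gbt_bundle, feature_matrix, tmp_path):
    path = tmp_path / "model.json"
    gbt_bundle.save(path)
    loaded = ub.ModelBundle.load(path)
    p1 = gbt_bundle.model.predict_proba(feature_matrix.X[:100])
    p2 = loaded.model.predict_proba(feature_matrix.X[:100])
    np.testing.assert_allclose(p1, p2, atol=1e-6)
    assert loaded.feature_names == gbt_bundle.feature_names
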