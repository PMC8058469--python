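import numpy as np
import pandas as pd
import pytest

from metaboscan import normalization, qc, variants
from metaboscan.classifier import (
    ClassifierError,
    auc_score,
    evaluate,
    fit_logitboost,
    predict_label,
    predict_proba,
    read_model,
    roc_curve,
    select_iterations,
    stratified_folds,
    write_model,
)


def _labels(values, index=None):
    return pd.Series(values, index=index or range(len(values)), name="group")


def _toy_four_point():
    features = pd.DataFrame({"x": [2.0, 2.0, -2.0, -2.0]},
                            index=["a", "b", "c", "d"])
    labels = _labels(["case", "case", "control", "control"],
                     index=["a", "b", "c", "d"])
    return features, labels


class TestFitLogitboost:
    def test_zero_iterations_gives_half(self):
        features, labels = _toy_four_point()
        model = fit_logitboost(features, labels, 0)
        proba = predict_proba(model, features)
        assert (proba == 0.5).all()

    def test_one_iteration_hand_computed(self):
        # at F=0: z = (2,2,-2,-2), w = 1/4; weighted OLS on x gives
        # F = x/2 and p = 1/(1+exp(-x))
        features, labels = _toy_four_point()
        model = fit_logitboost(features, labels, 1)
        proba = predict_proba(model, features)
        expected = 1.0 / (1.0 + np.exp(-features["x"].to_numpy()))
        np.testing.assert_allclose(proba.to_numpy(), expected, rtol=1e-12)

    def test_separable_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(2, 0.5, 10), rng.normal(-2, 0.5, 10)])
        noise = rng.normal(size=20)
        features = pd.DataFrame({"signal": x, "noise": noise})
        labels = _labels(["case"] * 10 + ["control"] * 10)
        model = fit_logitboost(features, labels, 50)
        preds = predict_label(model, features)
        assert (preds == labels).mean() == 1.0

    def test_single_class_rejected(self):
        features = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ClassifierError):
            fit_logitboost(features, _labels(["case"] * 4), 1)

    def test_selection_invariant_to_column_order(self):
        rng = np.random.default_rng(6)
        features = pd.DataFrame(rng.normal(size=(30, 6)),
                                columns=list("fedcba"))
        features["a"] = np.concatenate([rng.normal(1, 1, 15),
                                        rng.normal(-1, 1, 15)])
        labels = _labels(["case"] * 15 + ["control"] * 15)
        m1 = fit_logitboost(features, labels, 5)
        m2 = fit_logitboost(features[sorted(features.columns)], labels, 5)
        assert [bl.feature for bl in m1.base_learners] == \
            [bl.feature for bl in m2.base_learners]
        np.testing.assert_allclose(predict_proba(m1, features),
                                   predict_proba(m2, features), rtol=1e-12)

    def test_affine_rescaling_absorbed(self):
        rng = np.random.default_rng(7)
        features = pd.DataFrame(rng.normal(size=(40, 4)),
                                columns=["a", "b", "c", "d"])
        features["a"] += np.r_[np.ones(20), -np.ones(20)]
        labels = _labels(["case"] * 20 + ["control"] * 20)
        scaled = features.copy()
        scaled["a"] = scaled["a"] * 37.5 + 11.0
        m1 = fit_logitboost(features, labels, 10)
        m2 = fit_logitboost(scaled, labels, 10)
        np.testing.assert_allclose(predict_proba(m1, features).to_numpy(),
                                   predict_proba(m2, scaled).to_numpy(),
                                   atol=1e-8)


class TestPredict:
    def test_empty_model_is_half_everywhere(self):
        features, labels = _toy_four_point()
        model = fit_logitboost(features, labels, 0)
        assert (predict_proba(model, features) == 0.5).all()

    def test_four_point_model_at_zero(self):
        features, labels = _toy_four_point()
        model = fit_logitboost(features, labels, 1)
        at_zero = pd.DataFrame({"x": [0.0]}, index=["q"])
        assert predict_proba(model, at_zero)["q"] == pytest.approx(0.5)

    def test_probabilities_bounded(self):
        features, labels = _toy_four_point()
        model = fit_logitboost(features, labels, 20)
        wild = pd.DataFrame({"x": [-1e6, 0.0, 1e6]})
        proba = predict_proba(model, wild)
        assert ((proba >= 0) & (proba <= 1)).all()

    def test_missing_feature_named(self):
        features, labels = _toy_four_point()
        model = fit_logitboost(features, labels, 1)
        with pytest.raises(ClassifierError, match="'x'"):
            predict_proba(model, pd.DataFrame({"y": [1.0]}))


class TestStratifiedFolds:
    def test_partition_and_balance(self):
        labels = _labels(["case"] * 25 + ["control"] * 25)
        folds = stratified_folds(labels, 10, seed=4)
        assert sorted(folds.index) == sorted(labels.index)
        for f in range(10):
            counts = labels[folds == f].value_counts()
            # per-fold class counts within 1 of proportionality (2.5 each)
            assert abs(counts.get("case", 0) - 2.5) <= 0.5
            assert abs(counts.get("control", 0) - 2.5) <= 0.5

    def test_k_larger_than_class_rejected(self):
        labels = _labels(["case"] * 3 + ["control"] * 20)
        with pytest.raises(ClassifierError):
            stratified_folds(labels, 5, seed=0)

    def test_groups_share_folds(self):
        labels = _labels(["case"] * 8 + ["control"] * 8)
        groups = pd.Series([f"s{i // 2}" for i in range(16)],
                           index=labels.index)
        folds = stratified_folds(labels, 4, seed=1, groups=groups)
        for g in groups.unique():
            assert folds[groups == g].nunique() == 1


class TestSelectIterations:
    def test_deterministic(self):
        rng = np.random.default_rng(12)
        features = pd.DataFrame(rng.normal(size=(40, 5)))
        labels = _labels(["case"] * 20 + ["control"] * 20)
        a = select_iterations(features, labels, k=5, max_iterations=8, seed=3)
        b = select_iterations(features, labels, k=5, max_iterations=8, seed=3)
        assert a.selected_iterations == b.selected_iterations
        assert (a.folds == b.folds).all()
        np.testing.assert_array_equal(a.accuracy_curve, b.accuracy_curve)

    def test_strong_signal_selected_and_accurate(self):
        rng = np.random.default_rng(13)
        n = 60
        signal = np.r_[rng.normal(2, 0.7, n // 2), rng.normal(-2, 0.7, n // 2)]
        features = pd.DataFrame({"signal": signal,
                                 "noise": rng.normal(size=n)})
        labels = _labels(["case"] * (n // 2) + ["control"] * (n // 2))
        cv = select_iterations(features, labels, k=10, max_iterations=20,
                               seed=5)
        assert cv.selected_iterations >= 1
        assert cv.cv_accuracy > 0.9

    def test_curve_length_and_selection_rule(self):
        rng = np.random.default_rng(14)
        features = pd.DataFrame(rng.normal(size=(24, 3)))
        labels = _labels(["case"] * 12 + ["control"] * 12)
        cv = select_iterations(features, labels, k=4, max_iterations=6, seed=1)
        assert len(cv.accuracy_curve) == 7
        assert cv.cv_accuracy == cv.accuracy_curve.max()
        first_max = int(np.argmax(cv.accuracy_curve))
        assert cv.selected_iterations == first_max


class TestEvaluate:
    def test_perfect_predictions(self):
        rng = np.random.default_rng(15)
        x = np.r_[rng.normal(3, 0.3, 10), rng.normal(-3, 0.3, 10)]
        features = pd.DataFrame({"x": x})
        labels = _labels(["case"] * 10 + ["control"] * 10)
        model = fit_logitboost(features, labels, 30)
        report = evaluate(model, features, labels)
        assert report.accuracy == 1.0
        assert report.sensitivity == 1.0
        assert report.specificity == 1.0
        assert report.auc == 1.0

    def test_confusion_definitions(self):
        # TP=3 FP=1 FN=2 TN=4 -> sens .6, spec .8, acc .7
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        proba = np.array([.9, .8, .7, .2, .1, .6, .4, .3, .2, .1])
        from metaboscan.classifier import _evaluate_arrays
        report = _evaluate_arrays(y, proba)
        assert (report.tp, report.fp, report.fn, report.tn) == (3, 1, 2, 4)
        assert report.sensitivity == pytest.approx(0.6)
        assert report.specificity == pytest.approx(0.8)
        assert report.accuracy == pytest.approx(0.7)

    def test_all_equal_probabilities_auc_half(self):
        y = np.array([1, 1, 0, 0])
        assert auc_score(y, np.array([0.5] * 4)) == pytest.approx(0.5)

    def test_auc_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(16)
        for _ in range(20):
            n = int(rng.integers(6, 50))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            proba = np.round(rng.uniform(size=n), 1)  # force some ties
            wins = 0.0
            pos = proba[y == 1]
            neg = proba[y == 0]
            for a in pos:
                for b in neg:
                    wins += 1.0 if a > b else (0.5 if a == b else 0.0)
            brute = wins / (len(pos) * len(neg))
            assert auc_score(y, proba) == pytest.approx(brute)

    def test_roc_endpoints(self):
        y = np.array([1, 0, 1, 0])
        pts = roc_curve(y, np.array([.9, .8, .4, .1]))
        assert pts[0] == (0.0, 0.0)
        assert pts[-1] == (1.0, 1.0)
        fprs = [p[0] for p in pts]
        tprs = [p[1] for p in pts]
        assert fprs == sorted(fprs)
        assert tprs == sorted(tprs)

    def test_subgroup_reports(self):
        rng = np.random.default_rng(17)
        x = np.r_[rng.normal(1.5, 1, 20), rng.normal(-1.5, 1, 20)]
        features = pd.DataFrame({"x": x})
        labels = _labels(["case"] * 20 + ["control"] * 20)
        strata = pd.Series((["G1"] * 10 + ["G2"] * 10) * 2,
                           index=labels.index)
        model = fit_logitboost(features, labels, 10)
        report = evaluate(model, features, labels, subgroups=strata)
        assert set(report.subgroups) == {"G1", "G2"}
        merged = sum(r.tp + r.fp + r.fn + r.tn
                     for r in report.subgroups.values())
        assert merged == 40


@pytest.fixture()
def variant_inputs(default_dataset, default_normalized, default_filtered):
    return default_normalized, default_filtered, default_dataset.design


class TestVariants:

    def test_ratio_feature_count(self, variant_inputs):
        norm, filt, design = variant_inputs
        n = filt.n_metabolites
        data = variants.build_variant("ratios", norm, filt, design)
        assert data.features.shape == (144, n * (n - 1) // 2)

    def test_averaged_uses_all_channels(self, variant_inputs):
        norm, filt, design = variant_inputs
        data = variants.build_variant("averaged", norm, filt, design)
        assert data.features.shape == (144, 262)

    def test_ratios_plus_count(self, variant_inputs):
        norm, filt, design = variant_inputs
        n = filt.n_metabolites
        data = variants.build_variant("ratios_plus_metabolites", norm, filt,
                                      design)
        assert data.features.shape[1] == n * (n - 1) // 2 + n

    def test_raw_variant_keeps_replicates_together(self, variant_inputs):
        norm, filt, design = variant_inputs
        data = variants.build_variant("raw", norm, filt, design)
        assert data.features.shape == (288, 262)
        folds = stratified_folds(data.labels, 10, seed=2, groups=data.groups)
        for sid, rids in design.run_map.items():
            assert folds[rids].nunique() == 1

    def test_unknown_variant_rejected(self, variant_inputs):
        norm, filt, design = variant_inputs
        with pytest.raises(Exception, match="variant"):
            variants.build_variant("bogus", norm, filt, design)

    def test_78_channels_give_3003(self, default_normalized, default_dataset):
        norm = default_normalized
        filt78 = norm.subset_metabolites(norm.metabolite_names[:78])
        data = variants.build_variant("ratios", norm, filt78,
                                      default_dataset.design)
        assert data.features.shape[1] == 3003
        plus = variants.build_variant("ratios_plus_metabolites", norm, filt78,
                                      default_dataset.design)
        assert plus.features.shape[1] == 3081


class TestModelSerialization:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(18)
        features = pd.DataFrame(rng.normal(size=(30, 4)),
                                columns=["a", "b", "c", "d"])
        features["a"] += np.r_[np.ones(15), -np.ones(15)]
        labels = _labels(["case"] * 15 + ["control"] * 15)
        model = fit_logitboost(features, labels, 7)
        path = tmp_path / "model.tsv"
        write_model(model, path)
        back = read_model(path)
        assert back.n_iterations == model.n_iterations
        np.testing.assert_allclose(predict_proba(back, features).to_numpy(),
                                   predict_proba(model, features).to_numpy(),
                                   rtol=1e-12)
        assert back.positive == model.positive
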