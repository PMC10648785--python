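"""CV structure, metric formulas, AUC oracle, DeLong behaviour, importances."""

import numpy as np
import pandas as pd
import pytest

from scintrec.evaluation import (
    EvaluationError,
    ModelSpec,
    compare_auc,
    confusion_metrics,
    cross_validate_model,
    feature_importance,
    fit_predict,
    make_classifier,
    roc_auc,
    run_experiment,
    stratified_kfold,
)
from scintrec.synthetic import CohortSpec, cohort_to_frame, simulate_cohort
from scintrec.tabular import assemble

from oracles import auc_oracle


class TestStratifiedKfold:
    def test_exact_proportions_when_divisible(self):
        labels = np.array([1] * 10 + [0] * 40)
        fold_of = stratified_kfold(labels, k=5, seed=0)
        for f in range(5):
            assert labels[fold_of == f].sum() == 2
            assert (fold_of == f).sum() == 10

    def test_k_one_rejected(self):
        with pytest.raises(EvaluationError):
            stratified_kfold(np.array([0, 1, 0, 1]), k=1)

    def test_cohort_scale_pigeonhole(self):
        labels = np.array([1] * 101 + [0] * 253)
        fold_of = stratified_kfold(labels, k=5, seed=1)
        pos_counts = {labels[fold_of == f].sum() for f in range(5)}
        assert pos_counts <= {20, 21}

    def test_partition(self):
        labels = np.array([0, 1] * 10)
        fold_of = stratified_kfold(labels, k=5, seed=2)
        assert np.bincount(fold_of).sum() == 20 and fold_of.max() == 4


class TestConfusionMetrics:
    def test_reported_confusion_matrix_values(self):
        m = confusion_metrics(tn=219, fp=34, fn=19, tp=82)
        assert round(m["accuracy"], 2) == 0.85
        assert round(m["sensitivity"], 2) == 0.81
        assert round(m["specificity"], 2) == 0.87
        assert round(m["precision"], 2) == 0.71
        assert round(m["f1"], 2) == 0.76

    def test_perfect_classifier(self):
        m = confusion_metrics(tn=10, fp=0, fn=0, tp=5)
        assert all(m[k] == 1.0 for k in ("accuracy", "sensitivity", "specificity", "precision", "f1"))

    def test_always_negative_flags_precision(self):
        m = confusion_metrics(tn=253, fp=0, fn=101, tp=0)
        assert m["accuracy"] == pytest.approx(253 / 354)
        assert m["sensitivity"] == 0 and m["specificity"] == 1
        assert m["precision"] == 0 and "precision" in m["undefined"]

    def test_all_zero_rejected(self):
        with pytest.raises(EvaluationError):
            confusion_metrics(0, 0, 0, 0)


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scores_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_fixed_example_against_pair_count(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert roc_auc(scores, labels) == auc_oracle(scores, labels)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert roc_auc(scores, labels) == pytest.approx(auc_oracle(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc([0.1, 0.9], [1, 1])


class TestCompareAuc:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(0)
        s = rng.random(60)
        y = rng.integers(0, 2, 60)
        res = compare_auc(s, s, y)
        assert res.p_value == 1.0 and res.auc_a == res.auc_b

    def test_informative_vs_noise_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 500)
            informative = y + rng.normal(0, 0.6, 500)
            noise = rng.normal(0, 1, 500)
            res = compare_auc(informative, noise, y)
            hits += res.p_value < 0.01
        assert hits >= 18

    def test_variance_agrees_with_bootstrap(self):
        rng = np.random.default_rng(7)
        n = 300
        y = rng.integers(0, 2, n)
        sa = y + rng.normal(0, 1.0, n)
        sb = y + rng.normal(0, 1.4, n)
        deltas = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if y[idx].sum() in (0, n):
                continue
            deltas.append(roc_auc(sa[idx], y[idx]) - roc_auc(sb[idx], y[idx]))
        boot_var = np.var(deltas)
        # recover the DeLong variance from the z statistic
        res = compare_auc(sa, sb, y)
        from scipy import stats

        z = stats.norm.isf(res.p_value / 2)
        delong_var = ((res.auc_a - res.auc_b) / z) ** 2
        assert delong_var == pytest.approx(boot_var, rel=0.15)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(EvaluationError):
            compare_auc([0.1], [0.2, 0.3], [1, 0])


class TestModels:
    def test_all_models_fit_separable_toy_data(self):
        X = np.vstack([np.full((20, 2), 0.0), np.full((20, 2), 5.0)])
        X += np.random.default_rng(0).normal(0, 0.1, X.shape)
        y = np.array([0] * 20 + [1] * 20)
        for name in ("LR", "NB", "RF", "SVC", "XGB"):
            scores, clf = fit_predict(ModelSpec(name), X, y, X)
            assert np.mean((scores >= 0.5) == y) == 1.0, name

    def test_deterministic_scores_under_seed(self):
        rng = np.random.default_rng(1)
        X = rng.random((80, 6))
        y = rng.integers(0, 2, 80)
        for name in ("RF", "XGB"):
            a, _ = fit_predict(ModelSpec(name, seed=3), X, y, X)
            b, _ = fit_predict(ModelSpec(name, seed=3), X, y, X)
            assert np.array_equal(a, b), name

    def test_non_finite_features_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(EvaluationError, match="non-finite"):
            fit_predict(ModelSpec("LR"), X, np.array([0, 1]), X)


class TestFeatureImportance:
    def test_planted_feature_ranks_first(self):
        rng = np.random.default_rng(2)
        n = 300
        y = rng.integers(0, 2, n)
        X = rng.normal(0, 1, (n, 8))
        X[:, 3] = y + rng.normal(0, 0.2, n)
        clf = make_classifier(ModelSpec("RF", seed=0))
        clf.fit(X, y)
        names = [f"f{i}" for i in range(8)]
        imp = feature_importance(clf, names)
        assert imp.feature.iloc[0] == "f3"
        assert imp.importance.iloc[0] > imp.importance.iloc[1]

    def test_importances_normalized_and_tagged(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 4))
        y = rng.integers(0, 2, 100)
        clf = make_classifier(ModelSpec("RF", seed=0))
        clf.fit(X, y)
        names = ["age", "front_glcm_Contrast", "back_firstorder_Mean", "rp"]
        imp = feature_importance(clf, names, top=4)
        assert imp.importance.sum() == pytest.approx(1.0)
        tags = dict(zip(imp.feature, imp["class"]))
        assert tags["age"] == "clinical" and tags["front_glcm_Contrast"] == "radiomics"

    def test_non_ensemble_rejected(self):
        clf = make_classifier(ModelSpec("LR"))
        with pytest.raises(EvaluationError):
            feature_importance(clf, ["a"])


@pytest.fixture(scope="module")
def clinical_design():
    df = cohort_to_frame(simulate_cohort(CohortSpec(n_patients=120, seed=31)))
    return assemble(df, None, feature_set="clinical")


class TestCrossValidation:
    def test_pooled_confusion_totals_cohort(self, clinical_design):
        rep = cross_validate_model(clinical_design, ModelSpec("LR", "clinical"), seed=0)
        cm = rep.pooled_confusion
        assert cm["tn"] + cm["fp"] + cm["fn"] + cm["tp"] == 120
        assert len(rep.per_fold) == 5

    def test_permuted_labels_auc_near_half(self, clinical_design):
        import dataclasses

        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            shuffled = dataclasses.replace(
                clinical_design, y=rng.permutation(clinical_design.y)
            )
            rep = cross_validate_model(
                shuffled, ModelSpec("LR", "clinical", seed=seed), seed=seed
            )
            aucs.append(rep.per_fold["auc"].mean())
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_experiment_deterministic(self, clinical_design):
        designs = {"clinical": clinical_design}
        grid = (("LR", "clinical"), ("RF", "clinical"))
        r1 = run_experiment(designs, seed=5, grid=grid)
        r2 = run_experiment(designs, seed=5, grid=grid)
        pd.testing.assert_frame_equal(r1.metrics_table, r2.metrics_table)
        assert r1.best_label == r2.best_label
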