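import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from peptidiag.bench import (
    FAMILIES,
    DiagnosticBench,
    ModelSpec,
    crossval_roc,
    default_specs,
    reduce_dimensions,
    stratified_split,
)
from peptidiag.evaluate import single_feature_auc

from .conftest import synthetic_matrix


def labels_series(n_tc, n_hc):
    ids = [f"S{i:04d}" for i in range(n_tc + n_hc)]
    return pd.Series(["TC"] * n_tc + ["HC"] * n_hc, index=ids)


class TestStratifiedSplit:
    def test_study_scale_counts(self):
        split = stratified_split(labels_series(414, 430), seed=1)
        assert len(split.test_ids) == 83 + 86
        lab = labels_series(414, 430)
        test_lab = lab.loc[split.test_ids]
        assert (test_lab == "TC").sum() == 83
        assert (test_lab == "HC").sum() == 86
        assert set(split.train_ids).isdisjoint(split.test_ids)
        assert len(split.train_ids) + len(split.test_ids) == 844

    def test_small_balanced_counts(self):
        split = stratified_split(labels_series(10, 10), seed=0)
        lab = labels_series(10, 10).loc[split.test_ids]
        assert (lab == "TC").sum() == 2 and (lab == "HC").sum() == 2

    def test_seed_reproducibility(self):
        a = stratified_split(labels_series(50, 50), seed=9)
        b = stratified_split(labels_series(50, 50), seed=9)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(labels_series(10, 0), seed=0)


class TestBenchFit:
    def test_separable_toy_all_families_fit_training_data(self):
        m = synthetic_matrix(n_per_class=10, n_features=2, effect_features=(0,),
                             log2fc=5.0, cv=0.05, seed=6)
        split = stratified_split(m.labels, seed=0)
        # LGBM's default leaf/bin minima (20 and 3) cannot split 16 rows
        lgbm_hp = {"min_child_samples": 2, "min_data_in_bin": 1}
        specs = [ModelSpec(f, lgbm_hp if f == "LGBM" else {}) for f in FAMILIES]
        res = DiagnosticBench(m, specs=specs, seed=0).fit(split, cv_folds=2)
        Xtr = m.values.loc[split.train_ids].to_numpy()
        ytr = (m.labels.loc[split.train_ids] == "TC").to_numpy()
        for fam, model in res.models.items():
            assert (model.predict(Xtr) == ytr).all(), fam

    def test_constant_features_give_chance_auc(self):
        m = synthetic_matrix(n_per_class=40, n_features=3, effect_features=(),
                             seed=7, cv=1e-12)
        m.values.iloc[:, :] = 5.0
        split = stratified_split(m.labels, seed=0)
        specs = [ModelSpec("KNN"), ModelSpec("DecisionTree")]
        res = DiagnosticBench(m, specs=specs, seed=0).fit(split, cv_folds=2)
        for fam in res.models:
            assert res.metrics.loc[fam].auc == pytest.approx(0.5, abs=1e-9)

    def test_single_training_sample_rejected(self):
        m = synthetic_matrix(n_per_class=2, n_features=2, seed=8)
        split = stratified_split(m.labels, seed=0)
        split.train_ids, split.test_ids = split.train_ids[:1], split.test_ids
        with pytest.raises(ValueError):
            DiagnosticBench(m, seed=0).fit(split)

    def test_nonfinite_features_rejected(self):
        m = synthetic_matrix(n_per_class=5, n_features=2, seed=9)
        m.values.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            DiagnosticBench(m, seed=0)

    def test_test_rows_do_not_influence_training(self):
        """Altering held-out rows must leave the fitted models unchanged."""
        m1 = synthetic_matrix(n_per_class=20, n_features=4, seed=10)
        split = stratified_split(m1.labels, seed=0)
        m2 = m1.values.copy()
        m2.loc[split.test_ids] *= 100.0
        from peptidiag.peaks import FeatureMatrix

        m2 = FeatureMatrix(values=m2, labels=m1.labels, fill_mask=m1.fill_mask)
        specs = [ModelSpec("RandomForest"), ModelSpec("SVM")]
        r1 = DiagnosticBench(m1, specs=specs, seed=0).fit(split, cv_folds=2)
        r2 = DiagnosticBench(m2, specs=specs, seed=0).fit(split, cv_folds=2)
        probe = m1.values.loc[split.train_ids].to_numpy()
        for fam in ("RandomForest", "SVM"):
            np.testing.assert_allclose(
                r1.models[fam].predict_proba(probe),
                r2.models[fam].predict_proba(probe),
            )


class TestEvaluation:
    def test_perfect_probabilities_score_one_everywhere(self):
        m = synthetic_matrix(n_per_class=25, n_features=1, effect_features=(0,),
                             log2fc=8.0, cv=0.01, seed=11)
        split = stratified_split(m.labels, seed=1)
        res = DiagnosticBench(m, specs=[ModelSpec("RandomForest")], seed=1).fit(
            split, cv_folds=2
        )
        row = res.metrics.loc["RandomForest"]
        for metric in ("auc", "accuracy", "precision", "recall", "f1",
                       "mean_average_precision"):
            assert row[metric] == pytest.approx(1.0)
        cm = res.confusions["RandomForest"]
        assert cm[0, 1] == 0 and cm[1, 0] == 0

    def test_null_features_give_chance_auc_on_large_test_set(self):
        m = synthetic_matrix(n_per_class=2500, n_features=4, effect_features=(),
                             seed=12)
        split = stratified_split(m.labels, train_frac=0.6, seed=2)
        res = DiagnosticBench(m, specs=[ModelSpec("GaussianNB")], seed=2).fit(
            split, cv_folds=2
        )
        assert res.metrics.loc["GaussianNB"].auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_test_set_rejected(self):
        m = synthetic_matrix(n_per_class=20, n_features=2, seed=13)
        split = stratified_split(m.labels, seed=0)
        only_tc = [i for i in split.test_ids if m.labels[i] == "TC"]
        split.test_ids = only_tc
        res = DiagnosticBench(m, specs=[ModelSpec("GaussianNB")], seed=0).fit(
            split, cv_folds=2
        )
        with pytest.raises(ValueError):
            _ = res.metrics


class TestCrossvalRoc:
    def test_perfect_separability(self):
        m = synthetic_matrix(n_per_class=30, n_features=1, effect_features=(0,),
                             log2fc=8.0, cv=0.01, seed=14)
        _, _, aucs = crossval_roc(ModelSpec("RandomForest"), m, k=3, seed=0)
        assert aucs.mean() == pytest.approx(1.0)
        assert aucs.std() == pytest.approx(0.0)

    def test_null_features_near_half(self):
        m = synthetic_matrix(n_per_class=400, n_features=3, effect_features=(),
                             seed=15)
        _, _, aucs = crossval_roc(ModelSpec("GaussianNB"), m, k=5, seed=0)
        assert aucs.mean() == pytest.approx(0.5, abs=0.05)

    def test_bad_k_rejected(self):
        m = synthetic_matrix(n_per_class=10, n_features=2, seed=16)
        with pytest.raises(ValueError):
            crossval_roc(ModelSpec("SVM"), m, k=1)
        with pytest.raises(ValueError):
            crossval_roc(ModelSpec("SVM"), m, k=11)


class TestReduceDimensions:
    def test_pca_on_rank_two_data(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(80, 2))
        X = base @ rng.normal(size=(2, 10))
        m = synthetic_matrix(n_per_class=40, n_features=10, seed=17)
        m.values.iloc[:, :] = X - X.min() + 1.0
        coords = reduce_dimensions(m, "PCA", dims=2)
        from sklearn.preprocessing import StandardScaler
        from sklearn.decomposition import PCA

        p = PCA(n_components=10).fit(StandardScaler().fit_transform(m.values))
        assert p.explained_variance_ratio_[:2].sum() == pytest.approx(1.0, abs=1e-9)
        assert coords.shape == (80, 2)

    def test_pca_deterministic_up_to_sign(self):
        m = synthetic_matrix(n_per_class=20, n_features=5, seed=18)
        a = reduce_dimensions(m, "PCA")
        b = reduce_dimensions(m, "PCA")
        np.testing.assert_allclose(np.abs(a), np.abs(b), atol=1e-9)

    def test_separated_classes_have_high_silhouette(self):
        m = synthetic_matrix(n_per_class=50, n_features=10,
                             effect_features=tuple(range(5)), log2fc=3.0,
                             cv=0.1, seed=19)
        coords = reduce_dimensions(m, "PCA", dims=2)
        assert silhouette_score(coords, m.labels.to_numpy()) > 0.5

    def test_unknown_method_rejected(self):
        m = synthetic_matrix(n_per_class=10, n_features=3, seed=20)
        with pytest.raises(ValueError):
            reduce_dimensions(m, "LLE")


class TestAucInvariance:
    def test_auc_invariant_under_monotone_score_transforms(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60) + np.r_[np.ones(30), np.zeros(30)]
        labels = np.array(["TC"] * 30 + ["HC"] * 30)
        base = single_feature_auc(x, labels).auc
        for f in (np.exp, lambda v: v**3, lambda v: 5 * v - 2):
            assert single_feature_auc(f(x), labels).auc == pytest.approx(base)
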